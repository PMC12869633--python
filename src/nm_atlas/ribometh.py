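"""RiboMeth-seq MethScore from 5'/3' hydrolysis end profiles.

The end sum of position ``n`` is ``S_n = counts3[n] + counts5[n+1]``:
both read ends generated by cleavage of the bond 3' of ``n``.  The
MethScore compares ``S_n`` with the weighted mean end sum of the two
flanking neighbourhoods::

    L_n = sum_j w_j * S_{n-j} / sum_j w_j      (j = 1..F, F flanking nt)
    R_n = sum_j w_j * S_{n+j} / sum_j w_j
    MethScore_n = 1 - S_n / (0.5 * (L_n + R_n))

so a uniform profile scores exactly 0 and a fully protected bond
(``S_n = 0``) scores exactly 1.  The score estimates the methylated
fraction of transcripts at ``n``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidConfigError, MalformedInputError, UndefinedPositionError
from .riboxi import EndProfile


@dataclass
class MethScoreParams:
    flank: int = 2
    weights: tuple[float, ...] = (1.0, 0.9)
    clamp: bool = True

    def validate(self) -> None:
        if self.flank < 1:
            raise InvalidConfigError("flank must be >= 1")
        if len(self.weights) != self.flank:
            raise InvalidConfigError("need one weight per flank distance")
        if any(w <= 0 for w in self.weights):
            raise InvalidConfigError("weights must be positive")


@dataclass
class MethScoreTrack:
    """Per-position MethScore summary for one sequence.

    ``scores`` holds the replicate mean (NaN where undefined), ``end_sums``
    the replicate-summed S_n, ``replicate_sd`` the sample SD across
    replicates (NaN with < 2 replicates).
    """

    seq_id: str
    scores: np.ndarray
    end_sums: np.ndarray
    replicate_sd: np.ndarray
    n_replicates: int


def end_sum(profile: EndProfile, n: int) -> int:
    """S_n = 3' ends at n plus 5' ends at n+1."""
    if not 0 <= n < profile.length - 1:
        raise UndefinedPositionError(f"end sum undefined at {n} (length {profile.length})")
    return int(profile.counts3[n] + profile.counts5[n + 1])


def _end_sum_vector(profile: EndProfile) -> np.ndarray:
    return (profile.counts3[:-1] + profile.counts5[1:]).astype(float)


def methscore(profile: EndProfile, n: int, params: MethScoreParams | None = None) -> float:
    """MethScore at one position; NaN when both flank means are zero."""
    params = params or MethScoreParams()
    params.validate()
    s = _end_sum_vector(profile)
    f = params.flank
    if not f <= n <= s.shape[0] - 1 - f:
        raise UndefinedPositionError(f"flank of {f} does not fit around {n}")
    w = np.asarray(params.weights)
    # score = 1 - S_n / (0.5 * (L_n + R_n)); evaluated as a single ratio of
    # identically-computed weighted sums so a uniform profile cancels to
    # exactly 0 in floating point
    left = float(np.dot(w, s[n - f : n][::-1]))
    right = float(np.dot(w, s[n + 1 : n + 1 + f]))
    centre = float(np.dot(w, np.full(f, s[n])))
    if left + right == 0.0:
        return float("nan")
    score = round(1.0 - (centre + centre) / (left + right), 12)
    if params.clamp:
        score = min(1.0, max(0.0, score))
    return score


def _score_vector(profile: EndProfile, params: MethScoreParams) -> np.ndarray:
    s = _end_sum_vector(profile)
    f = params.flank
    out = np.full(profile.length, np.nan)
    for n in range(f, s.shape[0] - f):
        out[n] = methscore(profile, n, params)
    return out


def methscore_track(
    profiles: Sequence[EndProfile], params: MethScoreParams | None = None
) -> MethScoreTrack:
    """Replicate mean and sample SD of the MethScore per position."""
    params = params or MethScoreParams()
    params.validate()
    if not profiles:
        raise MalformedInputError("no replicate profiles")
    if len({p.length for p in profiles}) != 1:
        raise MalformedInputError("replicate profiles differ in length")
    per_rep = np.vstack([_score_vector(p, params) for p in profiles])
    defined = (~np.isnan(per_rep)).sum(axis=0)
    mean = np.full(per_rep.shape[1], np.nan)
    some = defined >= 1
    mean[some] = np.nanmean(per_rep[:, some], axis=0)
    sd = np.full(per_rep.shape[1], np.nan)
    if len(profiles) >= 2:
        mask = defined >= 2
        sd[mask] = np.nanstd(per_rep[:, mask], axis=0, ddof=1)
    sums = np.sum([np.concatenate([_end_sum_vector(p), [0]]) for p in profiles], axis=0)
    return MethScoreTrack(
        seq_id=profiles[0].seq_id,
        scores=mean,
        end_sums=sums,
        replicate_sd=sd,
        n_replicates=len(profiles),
    )
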