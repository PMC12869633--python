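# Methods

`nm-atlas` implements the computational side of profiling RNA
2′-*O*-methylation (Nm) with two complementary read-end assays, plus the
guide-matching and differential logic needed to assign Nm sites to box C/D
snoRNAs. Everything runs on synthetic data with planted truth, so every
stage can be validated by parameter recovery rather than by eye.

## The two assay models

**RibOxi-seq2 (positive signal).** Iterative periodate oxidation /
β-elimination removes unmodified nucleotides from fragment 3′ ends; only
fragments whose 3′-terminal ribose is 2′-*O*-methylated survive and accept
the sequencing linker. A read's 3′-terminal nucleotide therefore *is* the
Nm position. The simulator draws, per molecule, a uniform fragmentation
endpoint `e`, then resects 3′→5′ over at most `max_trim` nucleotides
(default 25 nt, the effective span of the oxidation cycles). Each scanned
position independently terminates the resection: with probability `f` at a
methylated site (stoichiometry `f`), and with probability `ε` anywhere
(incomplete oxidation; default 10⁻³, a free parameter — the chemistry has
no published rate). No stop within the window ⇒ the molecule is lost.
Equivalently, the read 3′ end is the *highest* firing position at or below
`e`, which is what produces the consecutive-site masking artefact: when
positions `p` and `p+1` are both fully methylated, a read can end at `p`
only if fragmentation happened exactly at `p`, so the upstream signal is
~1/(`max_trim`+1) ≈ 4% of its neighbour's and only the 3′-most site of a
tandem is observed. Surviving molecules receive a uniform 10-nt UMI and a
geometric number of PCR duplicates (mean `pcr_dup_mean`, default 1.5)
sharing UMI and coordinates.

**RiboMeth-seq (protection signal).** Alkaline hydrolysis cleaves each
internal phosphodiester bond independently; the bond 3′ of a methylated
nucleotide is protected in proportion to stoichiometry, so the bond after
position `n` is cleaved with probability `p₀·(1−f_n)` (`p₀` default 0.1
per molecule). Every cleavage leaves a fragment 3′ end at `n` and a 5′ end
at `n+1`; per-bond counts are sampled as Binomial(depth, p). Transcript
terminal ends are not cleavage events and are never counted.

## MethScore

With end sum `S_n = counts3[n] + counts5[n+1]`, flank width `F` (default
2) and weights `w_j` (defaults 1.0, 0.9 — decaying with distance;
configurable, stated here as package defaults):

    L_n = Σ_j w_j·S_{n−j} / Σ_j w_j        (j = 1..F)
    R_n = Σ_j w_j·S_{n+j} / Σ_j w_j
    MethScore_n = 1 − S_n / (½·(L_n + R_n))

This is the reading of the flanking normalisation under which a uniform
profile scores exactly 0 — the only fixed point consistent with "no
protection ⇒ no methylation". Scores are clamped to [0, 1] by default
(negative raw values arise from sampling noise; values above 1 are
impossible with non-negative counts); positions whose flank sums are both
zero are reported missing, not 0, because absence of fragments carries no
information. Numerically the score is evaluated as a single ratio of
identically computed weighted sums and rounded at 10⁻¹², so the uniform
fixed point is exact in floating point. Replicate summaries use the sample
(n−1) standard deviation and require ≥ 2 replicates.

## Nm score and peak calling

The paper-scale statistic is a per-position count: the Nm score of a
position is the summed, UMI-deduplicated 3′-end read count across a
condition's replicates (deduplication collapses on (sequence, strand,
3′-end, UMI); reads must be strictly longer than 20 nt). Whether the
published score is depth-normalised is not stated; the raw-count reading
is used and thresholds are scaled to depth instead. A position is called
when

* Nm score ≥ τ, and
* Nm score ≥ k × local background, with background = max(1, median of the
  3′-end track over ±50 nt excluding the position) and k = 5.

τ = 1000/500 are the high-confidence/permissive thresholds at full
sequencing depth (~30 M reads per sample); the experiments here run at
50,000 fragmentation attempts per transcript and use τ = 150, which under
the bounded-resection geometry (expected site count ≈
`f·depth·(max_trim+1)/L`) detects stoichiometries f ≳ 0.3 anywhere on a
transcript body. Adjacent super-threshold positions are reported
independently — sites are single-nucleotide by construction. Base-quality
filtering is out of scope (synthetic reads carry no qualities).

## Duplex MFE and canonical guide matching

Box C/D snoRNAs are annotated by motif: box C = 5′-most RUGAUGA, box D =
3′-most CUGA, box D′ = 3′-most CUGA lying ≥ 10 nt downstream of box C
*and* ≥ 10 nt upstream of box D (a D′ box must leave room for the D-box
guide; this also keeps chance CUGA instances inside a guide from stealing
the assignment). Antisense elements are the ≤ 15 nt immediately 5′ of a
D/D′ box, truncated at the sequence start or at the end of the upstream
box (C or D′); fewer than 10 nt ⇒ no usable guide.

Guide–target duplexes are scored with a hybridization-only dynamic
program: strictly monotone non-crossing pairings between antiparallel
strands, nearest-neighbour stack energies from a bundled Watson–Crick
table (Turner-style ΔG°₃₇ values) plus simplified G·U wobble stacks
(−1.2 kcal/mol with one wobble pair, −0.5 with two), an interior/bulge
penalty of +1.0 kcal/mol opening plus +0.4 per unpaired nucleotide with
the loop span capped at 6 nt per strand, and a +4.09 kcal/mol initiation
penalty. There is no intramolecular structure, no accessibility and no
dangling-end term, so absolute energies are *not* comparable with
RNAduplex/IntaRNA outputs; they are internally consistent, symmetric in
the two strands, and bit-reproducible. An exhaustive enumeration of all
admissible pairings (`brute_force_mfe`) validates the DP exactly on small
strands.

A canonical match over a site's ±7 nt window requires (i) the site
nucleotide Watson–Crick paired to the guide (wobble pairs participate in
the duplex but do not satisfy the site-pairing requirement), (ii) a
contiguous helix of ≥ 9 bp containing the site pair — scattered pairs
across interior loops do not count, since the methyltransferase is
positioned by a rigid duplex over the target — (iii) duplex energy
≤ −8 kcal/mol, and (iv) for the *canonical* flag, the guide nucleotide
paired to the site exactly 5 nt upstream of the box's 5′ nucleotide
(adjacent = 1). The +5 offset is measured from the box's 5′ side; the
gates in (ii)–(iii) are package defaults standing in for unpublished
filter values, and are configurable.

`make_guided_snoRNA` inverts the rule: it embeds the reverse complement
of the target window as the ASE so the site pairs at exactly +5, assembles
leader/spacers from an A/C alphabet that cannot form box motifs, and
self-checks with `canonical_match` before returning.

## Differential orphan-target logic

Target nomination is presence/absence, not a statistical test. "Present"
means Nm score ≥ τ_on; "missing" means ≤ τ_off (default 50 — strict zero
is brittle under sequencing noise; no numeric absence criterion is
published). SNORD116-style: present in both WT samples and missing in
both smDEL samples. SNORD113/114-style: present in the single
cluster-expressing sample and missing in the three others. Cluster
expression is supplied as sample metadata (it is genotype-determined, not
inferred). Surviving sites must additionally match a cluster snoRNA
canonically to be nominated. Site identity across samples is exact
(sequence, position, strand) — no slop window, matching the assay's
single-nucleotide resolution. Comparison consumes site tables called at a
permissive threshold so sub-τ_on scores remain visible to the absence
test; a site absent from a table counts as score 0.

## Metagene

Single-isoform transcripts carry two cut points (end of 5′UTR, end of
CDS); regions are half-open with the boundary nucleotide belonging to the
downstream region. The metagene coordinate scales each region onto its
own unit interval ([0,1) 5′UTR, [1,2) CDS, [2,3) 3′UTR). Multi-isoform
collapsing is out of scope — the synthetic transcriptome is isoform-free.

## Synthetic-data generator: what it does and does not emulate

The generator plants exact composition: site counts per region are
apportioned deterministically (largest remainder) over the region weights
(default 5% 5′UTR / 55% CDS / 40% 3′UTR, the observed mRNA mix), with
uniform positions within regions, no duplicate positions, and adjacent
sites allowed (they exist precisely to exercise the masking artefact).
Sites are never planted within 25 nt of a transcript end: a 3′ end at
position p supports reads of at most p+1 nt, so the > 20 nt read filter
blinds the first ~21 nt of a transcript, and MethScore flanks / duplex
windows need ±3 / ±7 nt of context. Transcript *length* geometry is a
separate knob from site placement: the experiments use region length
fractions (0.15, 0.50, 0.35) so that 5′UTRs are long enough (~60–120 nt)
to carry measurable sites, even though they host only ~5% of them.

Not emulated: sequencing errors, base qualities, adapters, alignment
ambiguity, multi-isoform structure, chemistry-specific distinctions
(Nm vs Ψm vs m⁵Um — both assays are chemistry-agnostic here, as in
practice), and transcript abundance variation (every transcript gets the
same molecule budget). Passing tests therefore demonstrate correctness of
the inference given the assays' idealised statistical structure, not
robustness to mapping artefacts or abundance-driven coverage bias.

## Study conditions used by the experiments

| experiment | conditions |
|---|---|
| MethScore recovery | one 240-nt transcript, sites at f ∈ {0, .25, .5, .75, 1}, 50,000 molecules × 3 replicates |
| RibOxi calling | 50 transcripts (400–600 nt), one site each, f ∈ {0.5, 0.75, 1}, depth 50,000, ε = 10⁻³, τ = 150 |
| Tandem masking | sites at p, p+1 with f = 1, ε = 0, depth 20,000 |
| Duplex oracle | 200 random strand pairs, lengths 3–12 |
| Guide recovery | 20 guides over ASE lengths 10–15 and both boxes; 100 shuffled-guide decoys |
| Orphan differential | 110 transcripts, 100 guide-independent sites (f ≥ 0.6) + 10 guide-dependent (f = 0.9 in WT only), depth 20,000, ε = 0, τ_on = 150, τ_off = 50 |
| Metagene | 500 sites at weights (0.05, 0.55, 0.40) over 200 transcripts |

These sizes keep each experiment in seconds on one core while leaving
comfortable statistical margins (per-site expected counts are ≥ 5× the
thresholds they must clear).

## Known limitations

* The Nm score is a raw count; cross-sample comparisons assume comparable
  depth, as the experiments guarantee by construction.
* Duplex energies are model-internal; only orderings and gate decisions
  are meaningful, not absolute kcal/mol.
* The masking model makes tandem-site recovery depend on `max_trim`; real
  libraries mix fragment chemistry in ways the single-parameter resection
  does not capture.
* The orphan logic is deterministic presence/absence; it has no notion of
  partial loss (e.g. a site dropping from f = 0.9 to 0.3 in the deletion).
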