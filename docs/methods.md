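# Methods

## Scope and model

`nickpair` models the geometry that determines whether a pair of Cas9
nickase/sgRNA complexes produces a heritable double-strand break (DSB),
and the statistics of the germline screens used to measure it. The
system modeled is SpCas9 and its single-domain nickase variants
(Cas9^D10A^, RuvC-dead; Cas9^H840A^, HNH-dead) directed by 20-nt sgRNA
spacers against NGG-PAM targets, as deployed in *Drosophila* germline
mutagenesis screens against the X-linked *white* gene.

All coordinates are 0-based, half-open, anchored to the plus strand of
a locus. A guide is stored by its plus-strand footprint `[start,
start+20)` regardless of strand, so every geometric formula lives in a
single frame; human-readable reports print 1-based inclusive intervals.

### Offset

The offset of a guide pair on opposite strands is the signed distance
between their PAM-distal (5′) spacer ends:

```
offset = start(plus-strand guide) − end(minus-strand guide)
```

Positive values mean the PAM-distal ends are separated with
outward-facing PAMs; negative values mean overlapping footprints (which
legitimately occur among the published *white* pairs) or inward PAMs.
This single formula is deliberately the only operationalization of the
verbal "PAM-distal end to PAM-distal end, positive when PAMs face
outward" convention: the outward/inward sign language describes the
common non-overlapping case, and the overlapping outward-PAM pair
white-D/white-R (printed offset −15) shows the footprint arithmetic,
not the PAM orientation, is what carries the sign. The formula
reproduces every sequence-anchored published offset (−15, −5, 6, 7).
Same-strand pairs carry no offset and are reported as `NA`.

### Nicks and overhangs

The cut register is fixed at 3 bp PAM-proximal inside the protospacer
(boundary between spacer positions 17|18 from the PAM-distal end), the
canonical SpCas9 blunt-cut register; it is exposed as the module
constant `CUT_REGISTER` because the source screens display the scissor
positions but never state the register, and because whether the RuvC
domain keeps exactly this register in vivo is not established. D10A
nicks the strand the sgRNA base-pairs with (opposite the protospacer
strand); H840A nicks the protospacer strand; WT cuts both (blunt DSB).

Two nicks on opposite strands leave a 5′ overhang when the plus-strand
nick lies left of the minus-strand nick, a 3′ overhang when right, and
a blunt end when equal; two nicks on one strand give no DSB. For
opposite-strand pairs the closed form is `length = |offset + 34|` with
D10A giving a 5′ overhang iff `offset + 34 > 0` and H840A giving the
complementary polarity at the same length (34 = 20 + 2·(20 − 17), the
footprint plus twice the register distance). The test suite checks the
closed form against the nick-bookkeeping implementation exhaustively
over offsets −100..100; offsets −45..−43 are skipped because no valid
placement exists there (the two PAM constraints demand different bases
at a shared position).

### Efficacy windows

Heritable mutagenesis requires a 5′ overhang plus an offset inside an
empirical window: `[−1, 26]` for D10A and `[−88, −35]` for H840A. The
D10A window is the published effective range; the H840A window is the
span of the observed effective screen rows (the qualitative statement
is only that offsets below −30 bp leave a 5′ overhang). Both windows
are configuration values, not hard-coded behavior. Single guides and
same-strand pairs are classified not-effective, mirroring the
observation that single nicks transmit at <0.1%.

## Off-target search

The off-target rule is a pure Hamming bound: every 20-mer on either
strand within `max_mm` mismatches (default 4) of the spacer, followed
on the same strand by NGG. All 20 positions weigh equally — no
seed-region weighting and no activity scores, because the rule being
modeled is a plain mismatch count. Genomic N counts as a mismatch and
never satisfies a PAM G position. The scan is a vectorized
shift-and-compare over the sequence (O(20·L) per strand), verified
against a per-base brute-force oracle on 50 kb fixtures; no index
structure is built because desk-scale loci are the intended input.

`paired_dsb_offtargets` asks the sharper question for nickases: among
the union of both guides' hits (each guide may pair with its own hits),
which opposite-strand hit pairs within a 200 bp span (configurable)
would themselves form an effective nick pair? The count of such
configurations versus single-guide hit counts is the specificity
argument for paired nicking.

## Screen statistics

The heritable mutation rate is mutant F1 over all F1 screened, as a
percentage; founder (G0) survival, fertility, and HDR-yielding rates
use the same arithmetic. Intervals are exact Clopper–Pearson (via the
beta-quantile closed form), chosen over Wald/Wilson because observed
rates include 0 and sub-1% values. Display rounding follows the source
reporting convention: one decimal at ≥1%, two decimals below 1%.
Censored cells ("<0.1%") and not-done cells are carried as distinct
sentinels and excluded from aggregates.

Aggregates over the published paired-rate tables (unweighted mean and
maximum of in-window rates, computed on the printed one-decimal values)
reproduce: D10A mean 11.2% and max 21.2% over the seven effective
pairs, H840A max 1.5%. The published single-sgRNA WT-Cas9 average of
53.1% is *not* reproducible as the unweighted mean of the printed
per-sgRNA rates (≈56.8% over distinct guides); it is presumably
F1-weighted with unpublished denominators and is treated as
out of reach rather than a golden value. Rate comparisons use the
two-sided Fisher exact test.

## HDR planning

An allele replacement is two homology-arm intervals on the wild-type
locus plus an insert; the predicted edited allele is the deterministic
splice `locus[0:left_arm.end) + insert + locus[right_arm.start:end)`.
Guides whose blunt cut boundary falls outside the replaced segment are
warned about, not rejected. Junction PCR is exact-match priming: a
primer amplifies where it occurs exactly once on the correct strand of
a template (ambiguity is an error); there is no melting-temperature or
mispriming model, because the modeled use of PCR is a presence/absence
junction check. A diagnostic junction pair — one primer across an
insert junction or inside the insert, the mate outside the arm — yields
a product on the edited allele only, a property the test sweep checks
on randomized designs. The published *piwi* design (0.96/1.1 kb arms,
4XP3-mCherry marker) is representable, but its element sequences are
not public; fixtures use synthetic stand-ins and real *piwi*
coordinates are out of scope.

## Synthetic data

**Mini-locus.** No accession exists for the screened *white* region,
but six printed spacers chain by ≥9-nt overlaps (rc(white-D)↔white-R
15 nt, R↔H 10, H↔I 9, I↔C 19, C↔A 17), forcing a unique 50-nt core
contig; with two synthesized 3-nt PAM flanks the mini-locus is 56 nt.
White-R's spacer strand fixes the contig plus strand (an arbitrary
global choice; all geometry is invariant under the flip, which the
tests check by reassembling from other seed guides). PAMs inside the
assembled evidence are taken as found — all four happen to be NGG,
an internal consistency check on the reconstruction — and the two PAMs
outside the evidence are synthesized as AGG, which only geometry never
reads. The remaining thirteen guides have no ≥9-nt overlap anchor and
are deliberately not placed; screen-table reproduction joins their
printed offsets from the table constants instead, so the offset checks
stay non-circular. The published table lists the white-E/white-A pair
at both offset 26 and offset 217; both cannot be sequence-true, and the
assembly manifest records the discrepancy without resolving it.

**Random genomes.** Seeded i.i.d. sequence at a target GC fraction
(default 0.42, fly-like), with off-target sites planted at exact
mismatch counts in non-overlapping 23-nt blocks and returned as a truth
manifest.

**Screen simulator.** Per founder: fertility is Bernoulli(`p_fertile`,
default 0.8, between the observed 42.9% and 100% founder fertilities);
a fertile founder's germline mutant fraction is Beta-distributed with
mean equal to the transmission probability of the pair's efficacy class
(default 0.1 effective / 0.001 not-effective, the latter mirroring the
<0.1% single-nick observation) and concentration 50 (moderate
founder-to-founder mosaicism); its clutch is a fixed `f1_per_g0`
(default 120, the order implied by published per-pair denominators)
with binomial mutant counts. The beta is mean-parameterized —
`Beta(κp, κ(1−p))` — so the estimator is unbiased for the class
transmission probability by construction. All randomness flows from
one explicit seed (default 1234).

What the simulator does *not* emulate: founder-to-founder clutch-size
variation, X-linkage/sex effects in scoring *white* eyes, somatic
mosaicism, multiple independent alleles per founder, and any sequence
dependence of activity. Passing recovery tests therefore shows the
estimator arithmetic and interval calibration are right under the
stated noise model, not that real screens behave this way.

## Numerical and testing choices

- Recovery checks run at ~21.5k simulated F1 (1,100 founders × 24 F1),
  where founder-level overdispersion contributes less variance than
  binomial sampling, making a 3-binomial-SE bound meaningful.
- The Clopper–Pearson coverage check at n=200, p=0.1 (true coverage
  96.7%, from exact enumeration) draws its 2,000 replicates by
  stratified inverse-CDF sampling, which estimates the coverage
  probability with error below 1/2000 and makes the check
  deterministic; an i.i.d. 2,000-draw estimate has a ~0.4-point
  standard error, larger than the distance from the true coverage to
  the nearest band edge.
- Fisher p-values come from `scipy.stats.fisher_exact`; the test suite
  cross-checks them against an independent hypergeometric tail sum.
- Tie-breaks: an overhang of length 0 between opposite-strand nicks is
  `blunt`; same-strand nick pairs are `none` (no DSB) with length 0;
  pair orientation at the degenerate coincident-PAM position classifies
  as `pam_in`.

## Known limitations

- The 3-bp cut register for the RuvC nick (H840A) is an assumption;
  staggered in-vivo registers would shift H840A overhang lengths by a
  constant without changing polarity classes.
- Efficacy windows are empirical, organism- and assay-specific; they
  are defaults, not biology that generalizes unchanged.
- The off-target scan is exhaustive but desk-scale; whole-genome use
  would want an indexed search and an activity model, both out of
  scope.
- The wet-lab rates themselves (e.g. that offset-7 pairs mutate at
  21.2%) are biological measurements; the package reproduces their
  arithmetic and geometry, not the biology.
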