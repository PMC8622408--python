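# Methods

## Scope and model of the data

`cresscan` treats a cyclovirus genome as a circular, covalently closed
single-stranded DNA molecule of roughly 1.7–1.9 kb with the canonical
ambisense organization: a capsid-protein (Cp) ORF on the virion-sense
strand, a replication-associated protein (Rep) ORF on the antisense
strand, a 5′-intergenic region (between the two initiation codons)
holding the origin of rolling-circle replication, and an optional
3′-intergenic region between the two stop codons. All coordinates are
1-based inclusive on the virion-sense strand; antisense features are
written `start > end` ("nt 1541–846" style), and regions may wrap the
circular origin.

## Ori and position one

The origin is marked by the nonanucleotide motif, consensus
`NAGTATTAC` (N = any base), at the apex of a stem–loop. The scanner
tests every circular window on both strands; an `N` in the genome
matches nothing (conservative for ambiguous base calls). Default
`max_mismatch = 1` accommodates the naturally occurring single-base
variants of the motif (e.g. `TACTATTAC`). When several windows tie on
mismatch count the hit with the best stem–loop wins (longest arms),
then the lowest position — the motif is only meaningful at the ori.

The stem–loop is found combinatorially rather than by thermodynamic
folding: over all loop placements (loop length 9–`max_loop`, default
13, containing the motif) arms are extended base by base under a
mismatch budget (`max_arm_mismatch`, default 1; terminal mismatches are
trimmed), and the structure maximizing arm length is kept (ties: a
smaller loop, then fewer arm mismatches; minimum arm 5 bp). For the
short, near-perfect hairpins these viruses carry, the maximal
complementary arm is the same structure a folding program exhibits,
and the search is exhaustively testable. No free energies are
computed.

After the hit is chosen the genome is reverse-complemented if needed
and rotated so the motif occupies positions 1–9 (ICTV position-one
convention). All downstream coordinates refer to this rotation.

## ORF calling and genetic codes

ORFs are enumerated on both strands, allowing wrap-around of the
circular origin, and must end at a stop codon. Within a stop-anchored
reading frame one ORF is reported, with its initiation codon chosen by
the start-preference policy: the 5′-most ATG; if the frame has none,
the 5′-most occurrence of each configured alternative start in list
order (default ATG, ATA, TTG, GTG). The initiation codon is always
translated as methionine. Candidates whose initiation codon overlaps
the ori motif (positions 1–9) are rejected. Defaults: `min_aa` 100 for
Rep/Cp candidates, 50 for incidental ORFs.

Genetic codes are NCBI translation tables 1, 4 and 5 (via Biopython's
codon tables), tried in that order; the annotator keeps the
lowest-numbered table whose best Rep carries all six conserved motifs
and records every alternative, reproducing the observed pattern that
most cycloviruses use the standard code while some require the
invertebrate mitochondrial code with an alternative initiation codon.

### Splice-aware Rep

Some Rep genes are interrupted by one short intron with canonical
GT…AG boundaries. The search considers every donor/acceptor pair with
intron length 4–`max_intron` (default 200 nt; observed cyclovirus
introns are tens of nt) on the antisense strand of the rotated genome,
requires excision to yield an in-frame, stop-free ORF whose start
codon lies wholly upstream of the donor and which crosses the splice
junction, and ranks candidates by (conserved-motif score, protein
length), breaking remaining ties toward the shorter intron and the
longer upstream exon. The implementation precomputes per-frame
next-stop and first-start tables so each candidate pair costs O(1);
a brute-force excision oracle checks it in the tests. A spliced
candidate is accepted only if it strictly beats the best unspliced
antisense candidate — and never when the unspliced Rep is already
motif-complete, since a "better" candidate could then only arise by
excising the genuine stop codon (a spurious intron). Introns spanning
the ori are not considered: the ori lies between the genes.

## Conserved motifs and the Arg-rich capsid terminus

Rep is scored against six degenerate consensus patterns from the
circovirus/cyclovirus literature (regular expressions, all
configurable): RCR-I `[FW]T[LIV]NN`, RCR-II `.[HPA][LIV][QH]G`,
RCR-III `Y[CLV][SK]K`, Walker A `G[PIAK][PST]GTGKS`, Walker B
`[LIVM][LIVM][FD]DD`, motif C `[LIVM]T[SN]N`. A zone constraint
(RCR motifs in the N-terminal half, SF3 motifs in the C-terminal half;
disable by flag) suppresses spurious cross-matches; for each motif the
leftmost in-zone match is reported. The motif score is the number of
distinct motifs found (0–6). The Cp arginine-rich region is quantified
as the (R+K) fraction of the N-terminal window (default 20 aa).

## Identities and demarcation

Pairwise identities use exact global Needleman–Wunsch alignment with
affine gaps (nucleotide: match +5, mismatch −4, gap open −10, extend
−0.5, `N` mismatches everything; protein: BLOSUM62 with the same gap
costs). The default "SDT-like" identity denominator counts all
columns except dual-gap and terminal-gap columns; an `ungapped` mode
excluding all gap columns is selectable. For near-identical pairs the
result is alignment-method-independent; for divergent pairs (~60 %)
different alignment dialects can move the value by a point or two, so
concordance with values computed by other programs is tolerance-based
(±2 points) rather than exact — the published identity convention for
such matrices is not fully specified. Genome-level identities are
computed on ori-rotated virion-sense sequences so linearization is
consistent.

Species demarcation is single-linkage clustering at ≥ 80 % genome-wide
nt identity (scipy connected components); the genus-support criterion
is > 55 % identity to a known cyclovirus. The genus call combines five
criteria: ambisense organization, ori on the Cp-encoding strand,
identity support, motif-complete Rep plus Arg-rich Cp, and tree
placement; "cyclovirus-like" requires the ori orientation plus at
least one other positive criterion, a genome whose motif strand
encodes the Rep-like protein is "circovirus-like", and a genome
without the motif is "unclassified".

## Phylogeny stand-in

Full maximum-likelihood inference is deliberately out of scope; the
package's claims about tree structure are coarse-topological (which
genomes are siblings), which distance methods reproduce. Neighbor
joining runs on distances `(100 − identity)/100` or alignment
p-distances, with deterministic lowest-index tie-breaking; a negative
branch length is clamped to zero and its deficit shifted to the
sibling edge, preserving the joined pair's path length. Bootstrap
supports resample alignment columns (default 100 replicates,
desk-scale; the field convention of 1000 is configurable) and report
the percentage of replicates containing each bipartition. Trees are
emitted unrooted (trifurcating seed node) as Newick; outgroup rooting
is available via `--root-on`. The sliding-window identity profile is a
lightweight visual screen for mosaic genomes; it flags crossovers but
performs no statistical recombination testing.

## Synthetic genomes and what they do (not) show

The generator plants, in position-one order: the motif opening the
stem–loop's loop (default arm 11 bp, loop 13 nt), the Cp ORF with a
planted (R+K) fraction in its N-terminal window, an optional 3′-IR,
the antisense Rep whose protein carries concrete instances of all six
motifs at fixed default offsets (15, 40, 70, 160, 190, 220), an
optional GT…AG intron, and spacers; a recorded random rotation is then
applied. Defaults emulate the published architectures: genome length
~1.7–1.9 kb (drawn via spacer lengths when not fixed), Rep 280 aa,
Cp 258 aa, 4-nt 3′-IR, standard code.

Truth is kept unambiguous by construction: an in-frame stop codon sits
immediately upstream of each planted initiation codon (anchoring the
start policy); internal methionines are excluded when the planted
start is not ATG; intron interiors are G-free (the only GT/AG
dinucleotides are the planted splice sites) and open with an in-frame
stop so the unspliced read-through never competes; for non-standard
codes the Rep carries two TGA-encoded tryptophans flanking the
helicase domain — too far apart for any single intron to excise — so
the standard code cannot produce a motif-complete Rep, and under
table 5 the Walker-A serine is encoded AGA (Arg under tables 1/4) so
only table 5 is motif-complete. Assembled genomes are re-drawn when a
spurious motif hit at least as good as the planted one appears.

The mutator applies independent per-site substitutions to a uniformly
chosen different base; the expected identity of a parent/mutant pair
is 100·(1−r) and of two independent mutants 100·((1−r)² + r²/3),
which the calibration checks reproduce within 1.5 points. Species
panels derive each species from an independent mutant of a shared root
(default between-rate 0.15 per site, within-rate 0.01), placing
within-species identities near 98 % and between-species identities
near 73 % — cleanly straddling the 80 % threshold. Panels are emitted
in the shared position-one rotation.

What the synthetic data does *not* model: insertions/deletions and
rate heterogeneity (real divergent pairs align with gaps),
compositional bias, sequencing ambiguity beyond `N` handling,
overlapping or additional ORFs, multiple introns, and recombination
other than the two-parent chimera used by the window-screen tests.
Passing the round-trip tests therefore demonstrates correctness of
the annotation logic under the canonical architecture, not robustness
to every irregular natural genome; annotation of real data should be
reviewed where warnings are emitted.

## Numerical and design choices

* Alignment tie-breaks among co-optimal alignments follow the
  aligner's deterministic first optimum; identity values for the exact
  (near-identical) checks are unaffected by this choice.
* Identity matrices are written to TSV at three decimals, the
  precision customarily printed for such tables.
* Test and acceptance batch sizes (500 oracle sequences, 200
  round-trip genomes, 100 panels, 30 random trees, 100 calibration
  replicates per rate) were chosen as the package's own desk-scale
  defaults; all are driven by explicit seeds and scale linearly.
* `rotate`, `revcomp` and region arithmetic are total functions with
  validated alphabets; degenerate inputs (empty files, non-IUPAC
  characters, linear-genome rotation, motif-free genomes) raise
  located errors or produce flagged-incomplete annotations rather than
  silent results.

## Known limitations

* ORFs are required to end at a stop codon; a hypothetical fully
  coding circle with no stop in frame is not reported.
* The spliced-Rep search considers one intron; start codons split by
  the intron are not considered.
* GenBank input is sequence-only (features ignored); annotation is
  always recomputed.
* The genus call is heuristic evidence aggregation, not a
  phylogenetic placement; borderline genomes should be inspected.
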