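# Methods

This note records the models, algorithms, parameter choices and known
limitations behind `panflux`, in the order the pipeline runs them.

## Constraint-based core

A model is a set of metabolites (optional element-count formula and integer
charge; either may be unknown) and reactions (stoichiometry, flux bounds in
mmol·gDW⁻¹·h⁻¹, a GPR boolean tree, a spontaneous flag, annotations), plus
a biomass objective. Boundary reactions are recognized structurally —
exactly one participating metabolite — and classified by id prefix
(`EX_`, `SK_`/`sink_`, `DM_`; the dialect is configurable).

**GPR algebra.** AND = enzyme complex, OR = isoenzymes. The *empty* rule
evaluates true: orphan and spontaneous reactions must survive strain
derivation, since curated references legitimately contain gene-less
reactions. Loss of genetic support is expressed by a distinct
*unsatisfiable* marker produced by substitution (a leaf whose replacement
set is empty becomes false; false propagates through AND and is pruned from
OR). Trees are kept in a flattened normal form so parse/serialize
round-trips are the identity.

**Balance checking** nets every element and the charge over the
stoichiometry. Three verdicts: `balanced` (all exactly zero), `unbalanced`,
and `undetermined` (any participant with unknown formula or charge, and all
boundary reactions by convention). `undetermined` is deliberately distinct
from `unbalanced`: lumped or poorly annotated metabolites should not block
reference expansion by default (a `block_undetermined` switch flips this).

**FBA** maximizes the objective flux subject to S·v = 0 and the bounds, as
a HiGHS linear program. A blocked objective is reported *optimal with value
0*; `infeasible` is reserved for genuinely contradictory constraints (e.g.
a forced maintenance flux with no energy source). Only the optimal value is
contractual — phenotype calls never depend on which optimal flux vector the
solver returns. Growth threshold: 1e−6 for "nonzero" inside the core, 1e−4
for phenotype calls (both overridable).

**Orphan accounting** counts internal, non-spontaneous reactions with an
empty GPR whose name does not contain "diffusion" (case-insensitive); the
fraction is taken over the same eligible denominator. Note that biomass and
maintenance pseudo-reactions count as orphans under this definition, as
they do in real reconstructions.

**I/O.** A JSON dialect (documented in `panflux/io.py`) round-trips every
field including cluster-space GPRs. SBML L3+FBC goes through COBRApy; the
spontaneous flag and "charge unknown" travel in SBML notes because FBC has
no native slot for either, and a configurable sentinel gene id (default
`spontaneous`) in a GPR is converted to flag + empty rule on load.

## Quality control

N50 is the length of the contig at which the descending cumulative contig
length first reaches half the assembly. Strains must satisfy all four
thresholds — missing ≤ 2%, fragmented ≤ 100%, N50 ≥ 50,000 bp, contigs
≤ 200 by default — with *inclusive* comparisons: a strain exactly at a
threshold is kept, which also makes filtering monotone under threshold
loosening. Completeness percentages are consumed from a TSV rather than by
running an ortholog-database scan; only those two numbers are used.

## Pangenome

**Alignment.** Identity = identical aligned residues / length of the
shorter sequence; coverage of a sequence = fraction of it inside the
aligned core (terminal overhangs excluded). Alignments are semi-global
(global with free end gaps) via Biopython's `PairwiseAligner` (match 2,
mismatch −1, gap open −5, extend −0.5); a banded edit-distance pre-screen
(edlib, infix mode, band = (1 − min identity + 0.25)·len) rejects hopeless
pairs cheaply. A plain edit-distance alignment is *not* used for the final
statistics: minimum-edit paths scatter spurious matches through overhang
regions and corrupt coverage. The synthetic world engineers identity
margins (≥ 0.95 within a family, ≪ 0.4 between) so that no threshold call
depends on the scoring scheme.

**Clustering** is greedy and incremental: sequences sorted by length
descending (ties by gene id), each joining the best-scoring
(identity × min coverage) existing cluster whose representative it matches
at identity ≥ 0.90 and both coverages ≥ 0.70, else founding a new cluster.
Best-match (not first-match) assignment and the fixed ordering make the
result deterministic. This is an exact desk-scale re-implementation of the
usual k-mer-prefiltered greedy clustering; correctness was preferred over
speed.

**PAM.** Clusters × strains; cells hold member gene ids and form a
partition of all genes. Premature-stop genes are tracked (TSV: trailing
`!`) because derivation discounts them.

**Gene recovery** (per strain, against genome + GFF3; GFF 1-based
inclusive coordinates converted to 0-based half-open at the boundary):

* *(i) split ORFs* — adjacent same-strand calls ≤ 400 bp apart whose
  concatenated translation matches a cluster representative at the
  clustering thresholds become one recovered record flagged
  `premature_stop=True`, replacing both parts in the PAM.
* *(ii) overlooked genes* — unannotated regions ≥ 60 bp are six-frame
  translated; stop-free stretches ≥ 20 aa are searched against
  representatives of clusters *empty for that strain*; hits meeting the
  thresholds are recovered intact (`premature_stop=False` unless an
  internal stop interrupts the aligned span).
* *(iii) truncated calls* — each annotated gene is extended in frame into
  adjacent unannotated sequence up to the next stop; an extension ≥ 10 aa
  that matches a representative produces a recovered record flagged
  `premature_stop=True` and **replaces** the partial call in the PAM. We
  chose replacement over coexistence because the partial call is an
  annotation artifact of the same locus; keeping both would break the
  PAM's partition property.

Overlapping candidates at one locus are resolved by highest identity, then
longest, then lexicographic order. The window sizes (400 bp, 60 bp, 20 aa,
10 aa) are package defaults exposed in `RecoveryParams`; they are generous
for the error modes modeled and not sensitive in the engineered worlds.

## Reference-free carving and gap-filling

Cluster representatives are aligned one-way against the universe's gene
sequences; a pair supports when identity ≥ 0.40 and the universal gene is
covered ≥ 0.70, scored identity × coverage. These thresholds are package
defaults (exposed in `HomologyParams`); one-way alignment (rather than BRH)
matches how reference-free methods transfer content. Each universe GPR is
rewritten by substituting every universal gene with the OR of its
supporting clusters; the reaction is carved in only if the rewritten rule
is satisfiable or the reaction is spontaneous — a complex with one
unsupported subunit is excluded outright rather than included with an
impaired GPR. Exchanges are added for every retained extracellular
metabolite with bounds (0, 1000); media later open uptakes. Carving is
monotone in support.

**Penalties.** Fractional support of a GPR = max over OR branches, min over
AND members, of the best per-gene score (0 if unsupported; the empty rule
counts as 1). Penalty = p_min + (1 − support)·(p_max − p_min) with
p_min = 0.1, p_max = 10; spontaneous and boundary reactions get p_min. The
formula is a deliberate, isolated concretization of "penalties from
alignment metrics" — alternatives plug in behind `compute_penalties`.

**Gap-filling** is solved exactly: binary indicator per candidate
repository reaction, big-M coupling lb·y ≤ v ≤ ub·y, steady state, a lower
bound min_flux on the objective variable, minimizing total penalty (MILP,
HiGHS). Among equal-penalty optima the result is made deterministic by
re-solving while forcing candidates out in descending id order, which
prefers keeping lexicographically small reaction ids. Infeasibility (even
the full repository cannot reach min_flux) is reported without mutating the
input. A post-hoc FBA re-verifies the augmented model. Exactness is
affordable because repositories here are pan-scale, not database-scale.

## Reference expansion

BRH ortholog pairs use score = identity × min coverage with identity ≥ 0.40
and both coverages ≥ 0.70; bitscores would add a substitution-matrix
dependency without changing calls at these margins. Each reference gene is
assigned to the cluster holding the **majority** of its BRH partners across
strains (ties to the smallest cluster id; conflicts are logged) — a simple,
auditable consolidation rule, isolated so it can be swapped. Reference
genes with no partner become placeholder leaves (`refonly__<gene>`): the
reaction stays in the pan-model, but every strain derivation sees the leaf
as absent, reconciling "pan contains the reference" with "strains carry
only supported content".

Expansion walks draft reactions absent from the translated reference,
re-resolves their metabolites with reference-priority definitions
(user overrides take precedence over both), re-checks balance, and adds the
candidate unless `unbalanced`. Biomass and the NGAM reaction (configurable
id, default `ATPM`) keep reference bounds bit-exactly. Finally, every
remaining reference orphan whose id the draft models with a non-empty GPR
gets that cluster-space GPR copied in — supplementation never overwrites a
non-empty rule and therefore never increases the orphan count.

## Strain derivation and phenotypes

A cluster counts present for a strain iff the strain's PAM cell holds at
least one gene **without** a premature stop — one intact isoform rescues
the cluster. GPR substitution then maps cluster leaves to the strain's
intact genes; unsatisfiable reactions are removed, then metabolites used by
no remaining internal reaction are pruned together with their boundary
reactions. Orphan, spontaneous and (empty-GPR) biomass reactions ride
along. Gap-filling against the pan-model runs per medium in order (later
rounds see earlier additions) with uniform penalties unless a table is
supplied — the alignment-derived penalties are an autopilot-level device;
at strain level the pan is already curated content. Default
min_flux = 0.001; gap-filling can be skipped entirely (auxotrophy studies
on minimal media). The default minimal aerobic medium opens glucose,
ammonia, phosphate and sulfate (sole C/N/P/S sources, rate 10), o2/h2o/h,
and a CarveMe-style trace-ion list, restricted to exchanges the model
actually has.

**Phenotypes.** Substrate tests swap the element's default source for the
candidate at the same uptake rate, keeping calls comparable; candidates
without an exchange score 0. Auxotrophy is defined as *biosynthetic
incapacity*: maximize a temporary demand for the cytosolic compound on the
minimal medium with the compound's own uptake closed; < threshold ⇒
auxotrophic. This demand-based definition is robust when the minimal
medium itself does not support growth (the growth-rescue variant is the
obvious alternative and can be built from the same primitives); a compound
the model does not represent scores auxotrophic with a warning, a target
metabolite absent from the model scores 0 for biosynthesis. All calls
depend only on LP optima, never on flux-vector degeneracy.

## Multi-strain analysis

BFTs merge by row concatenation over one strain set; constant rows are
kept by default (they legitimately shrink Jaccard distances) with an
explicit drop flag, and a feature exclusion list supports removing e.g. a
pathway's reaction block before tree building. Distance = 1 − Jaccard over
1-feature sets (a both-empty pair is at distance 0). Ward clustering runs
on these distances via the Lance–Williams recurrence — numerically
identical to SciPy's `linkage(…, "ward")`, which serves as the test oracle
— accepting the usual caveat that Jaccard distances are not Euclidean
embeddings. Ties merge the lexicographically smallest label pair, making
the tree deterministic. Cutting at k undoes the k−1 last merges; clusters
are labeled `Cluster_1..k` by decreasing size. Characteristic features are
ranked by freq(f, cluster) − freq(f, complement). Confusion metrics against
experimental {0,1,NA} tables exclude NA cells and report undefined ratios
as missing (NaN), never as zero.

## Synthetic world

The generator emulates: a universe of 34 reactions (lumped catabolism,
a two-subunit respiratory complex, a glucose-transporter isoform pair,
four spontaneous "diffusion" reactions, biomass, exchanges; core
metabolites carry real BiGG-style formulas/charges so transport, urease
and isomerase reactions are provably balanced, while lumped species stay
formula-less and hence `undetermined`); 19–20 gene families (lengths
120–300 aa) with per-strain variants at ≤ 2.5% substitutions; 20 strains
in three groups distinguished by a xylose module (+tryptophan synthase), a
histidine decarboxylase (−tryptophan synthase ⇒ planted auxotrophy), and
urease (+transporter); genomes as CDS concatenations with 500–2500 bp
random spacers padded to ≥ 52 kb so default QC passes; GFF3 with planted
defects in designated strains (split ORF, omitted gene, truncated call)
and one planted single-gene deletion creating an exactly-one-reaction gap;
a curated reference covering the core plus tryptophan synthase, with one
curated orphan (the glucose transporter) and an NGAM reaction forced at
0.5; completeness tables; a study medium (minimal + tryptophan, so the
planted auxotrophs grow and gap-filling cannot mask the auxotrophy).

What it does **not** emulate: realistic codon usage or operon structure,
phylogenetic sequence divergence, paralogy/domain shuffling (between-family
identity is essentially random), fragmented assemblies, contamination, or
database-scale universes. Passing tests therefore demonstrate algorithmic
correctness under unambiguous homology margins, not robustness to the
twilight zone of sequence similarity — on real data the alignment
thresholds, not the logic, carry the risk. Generation is a pure function of
(seed, parameters); problem sizes throughout the suite (20 strains, ~300
genes, 34-reaction universe, ≤ 12 gap-fill candidates for the enumeration
oracle) were chosen so every planted truth is exactly checkable.

## Numerical choices and degenerate inputs

LP/MILP: HiGHS defaults; gap-fill penalty ties broken at 1e−6 relative
tolerance; growth thresholds as above. Balance: |net| > 1e−9 counts as
imbalance. Ward: distances are guaranteed real under Lance–Williams since
the merged pair always attains the current minimum. Empty models, empty
media, single-strain consensus, k = 1 and k = n cuts, and both-empty
Jaccard pairs are all defined and tested. Errors are raised (not warned)
for namespace violations: unknown strains, GPR leaves that are neither PAM
clusters nor placeholders, duplicate ids, dangling objectives.
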