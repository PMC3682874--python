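# Methods

This note documents the model behind `cliquesum`, the defaults it ships with,
the decisions taken where the design was genuinely open, and what the
synthetic test harness does and does not establish.

## The predication graph

The unit of input is a predication *occurrence*: one extracted
subject–PREDICATE–object instance from one sentence of one citation, read from
a 9-column TSV modeled on the SemMedDB `PREDICATION` table. Occurrences
collapse into *distinct predications* keyed by (subject, predicate, object);
a distinct predication's frequency is the number of distinct citations
supporting it — repeated mentions inside a sentence or a citation count once.

The graph places one node per concept and one arc per unordered concept pair;
the arc holds every distinct predication between the pair, in either
direction and under any predicate. Degree centrality and cliques are defined
on this undirected simple view: multiplicity never inflates degree, because a
pair contributes exactly one arc. Direction (subject→object) is retained as
per-predication metadata. Self-predications are rejected at load time, since
centrality normalization and clique enumeration presuppose a simple graph.

Concept names and semantic types can differ across occurrences of one
concept; the graph stores the union of semantic types in sorted order and the
lexicographically smallest name, which makes construction invariant to record
order. Metapredication assignment therefore tries an argument's types in
sorted order and takes the first that yields an allowed triple.

## Condensation

Three filters run in a fixed order; each returns a subgraph plus a report
(before/after counts, the cutoff used, warnings).

* **Novelty.** Predications with a generic argument are removed. Generic
  concepts come from an explicit list and/or, when a concept hierarchy is
  supplied, from a depth rule: every concept closer than `generic_depth`
  levels to a hierarchy root is generic. No public default depth exists, so
  the hierarchy route is entirely user-configured; the bundled default ships
  a small explicit list ("Patients", "Pharmaceutical Preparations", …).
* **Centrality.** Freeman degree centrality `deg/(n−1)` is computed on the
  post-novelty graph. The cutoff is the arithmetic mean of all node
  centralities plus half their standard deviation; a predication survives
  only if **both** arguments score strictly above it.
* **Frequency.** Citation frequencies of the predications that survived the
  centrality filter set a second `mean + sd/2` cutoff; predications strictly
  below it are eliminated (equality survives — "below the cutoff" is read
  literally, mirroring the strict "above" on the centrality side). Both
  inequalities and the `sd` multiplier (default 0.5) are configurable.

Numerical conventions: standard deviations are population standard deviations
(the value set is the entire population of nodes or predications, not a
sample). Degenerate populations are not filtered: fewer than two values, or a
zero-variance population — where the strict centrality inequality would
otherwise delete the whole graph, e.g. on a degree-regular graph — skip the
cutoff with a warning. An empty post-filter graph is a warning, not an error;
the pipeline short-circuits and emits an empty summary with exit code 0.

## Cliques and co-membership

Maximal cliques are enumerated with Bron–Kerbosch with pivoting (via
`networkx.find_cliques`); the test suite and the acceptance script verify the
output against an exhaustive subset-enumeration oracle on small random
graphs. The default minimum clique size is 3 — dyads are not cliques in the
social-network tradition this pipeline descends from — configurable down
to 2. Output order is deterministic: descending size, then lexicographic
member list, with ids assigned 1..k.

The co-membership matrix S has shared-node counts off the diagonal and clique
sizes on it; S is the sole input to clustering, so clustering sees argument
overlap only (predicate similarity is deliberately not part of the distance —
a known limitation, see below).

## Clustering and the silhouette baseline

Clustering is agglomerative on similarity S, Johnson-style: at each step the
most similar cluster pair merges, and all pairs tied at the top similarity
merge simultaneously (tied chains collapse into one multi-way merge). One
partition is emitted per distinct merge height — the rows of an icicle plot,
finest to coarsest. Average linkage is the default; single and complete
linkage are options. A hand-rolled implementation is used because standard
binary-tree linkage routines sequence tied merges arbitrarily and cannot
express the simultaneous-merge contract; on tie-free inputs the tests
cross-check behavior against independent formula evaluation.

The baseline converts similarity to distance by max-shift
(`d = max off-diagonal − S`, zero diagonal) and evaluates the average
silhouette coefficient of every non-trivial row (2 ≤ k ≤ n−1 clusters).
Cliques in singleton clusters contribute silhouette 0 (the
Kaufman–Rousseeuw convention). The ASC-maximizing row is the baseline
partition; ties go to fewer clusters, the more summary-like choice. The
max-shift conversion is one of several defensible normalizations; it
preserves the ordering of similarities, which is all the silhouette uses.

## Theme labels and solution selection

The bundled configuration aggregates UMLS semantic types into 15 coarse
semantic groups and SemRep predicates into 7 predicate groups, and declares
8 allowed metapredication families (18 triples), e.g. "Drug treatment" =
`<Chemicals & Drugs> <Therapy> <Disorders>`. A cluster's predications (those
with both arguments inside some member clique — predications spanning two
cliques in different clusters belong to both clusters) are each assigned a
triple; the most frequent triple labels the cluster. Counting is over
distinct predications; summed citation frequency breaks ties, then the
configured triple order. Unmapped predications stay in the cluster but do not
vote; an all-unmapped cluster is UNLABELED.

Selection scans the icicle rows finest→coarsest. The starting row is the
first with at most `max_singletons` (default 3) singleton clusters; the
all-singleton row is never a candidate, and if no row qualifies the coarsest
row is used. From the starting row the walk adopts the next row while the
merge events between the rows are label-consistent. The conservative reading
— **every** event between consecutive rows must merge same-label,
non-UNLABELED clusters — is the default, because a single inconsistent merge
means the coarser row has already conflated two themes; a permissive mode
(any one consistent event suffices) is available.

The dynamic cut starts from the selected row and walks the remaining merge
events of the tree in order, applying an event only when all the current
clusters it touches share one non-UNLABELED label and skipping it otherwise
(without stopping); merged clusters are relabeled as it proceeds. The result
cuts different branches at different heights and need not coincide with any
icicle row.

## Validity and the MeSH comparison

Per labeled cluster, `x` counts in-cluster predications matching the label,
`y` the rest, and `z` the distinct predications in *other* labeled clusters
matching the label — each counted once however many other clusters hold it,
and never double-counting predications already inside the cluster. Cohesion
`x/(x+y)`, separation `x/(x+z)`, overall validity their harmonic mean.
Degenerate denominators report as missing rather than zero. Corpus scores are
computed both micro (pool x, y, z, then apply the formulas — the headline)
and macro (mean of per-cluster scores); UNLABELED clusters are excluded and
reported.

The MeSH comparison builds, per cluster, the major-descriptor multiset of the
citations contributing predications, ranks descriptors by citation count
(ties lexicographic), and truncates to k = the number of distinct cluster
concepts. Concepts match descriptors case-insensitively by name or through a
user-supplied synonym table; matching is one-to-one, greedy in descriptor
rank order. Recall divides matches by the reference descriptors actually
taken (≤ k when fewer exist), precision by the cluster concept count, so the
two can differ; cluster counts pool into corpus recall/precision/F.
Descriptor qualifiers ("/therapeutic use") are stripped on load, making the
scores invariant to qualifier strings.

## The synthetic harness

`synthetic.generate` plants `n_themes` themes of `concepts_per_theme`
concepts each. A theme is a circulant ring C_m(1, …, w−1) with window w = 3:
every pair of concepts within a sliding window of three consecutive ring
positions is connected. This shape was chosen over a single dense blob for
two structural reasons: it is degree-regular, so a clean corpus passes the
strict centrality cutoff via the zero-variance rule instead of being deleted
by it; and it yields m overlapping window cliques per theme, so the correct
k-theme partition appears as an icicle row with zero singleton clusters —a
partition of one-clique-per-theme singletons could never be selected under
the starting-row rule. Recovery is exact for m ≥ 6 (below that the ring
degenerates toward a complete graph and the themes collapse to single
cliques).

Each theme uses one predicate and one semantic type chosen so every planted
predication maps to the same metapredication family (defaults: Substance
interaction, Disease comorbidities, Body location, Etiology, Affect). Planted
citation counts default to a constant 8 per predication: the frequency
cutoff is `mean + sd/2` with strict-below elimination, so any spread within
the planted population would cut planted arcs and fragment the planted
cliques; the over-dispersion knob (`citation_dispersion`, negative-binomial
variance `μ + αμ²`) exists for stress tests rather than for the recovery
conditions. Noise predications connect a separate sparse concept pool with
mean citation count 1.5, a configurable fraction carrying generic arguments;
the frequency *contrast* between themes and noise is what gives the frequency
filter its signal. Optional bridge concepts join a window clique of adjacent
themes to exercise clique overlap; they break degree regularity and are
therefore off by default.

What passing the planted-recovery tests shows: the pipeline's stages compose
correctly and the semantic selection recovers block structure that the
generator makes unambiguous. What it does not show: performance on real
SemRep output, whose degree and frequency distributions are heavy-tailed,
whose themes are semantically mixed, and whose predications carry extraction
and word-sense errors — none of which the generator models.

## Defaults at a glance

| Parameter | Default | Meaning |
|---|---|---|
| `sd_multiplier` | 0.5 | cutoff = mean + multiplier × population sd |
| `min_clique_size` | 3 | smallest reported maximal clique |
| `linkage` | average | cluster similarity aggregation over S |
| `max_singletons` | 3 | starting-row tolerance in solution selection |
| `selection_mode` | conservative | all merge events must be label-consistent |
| `concepts_per_theme` | 7 | ring size per planted theme (≥ 6 for exact recovery) |
| `citation_mean` / `citation_dispersion` | 8.0 / 0.0 | planted citation counts |
| `noise_citation_mean` | 1.5 | noise citation counts |
| `generic_noise_fraction` | 0.3 | noise predications with a generic argument |

## Known limitations

* Clique similarity ignores predicates; two cliques sharing concepts but
  asserting unrelated relations still cluster together.
* The bundled semantic-type map covers the common UMLS type abbreviations,
  not the full inventory; unmapped types silently yield unmapped
  predications. Users with UMLS access should supply a complete map.
* The asterisk markers attached to some predicates and triples in the source
  vocabulary tables have no accompanying restriction text; the bundled
  configuration includes those rows unconditionally and users may override.
* Corpus-scale behavior (tens of thousands of citations) is untested here;
  the clustering implementation is quadratic per merge step and intended for
  the tens-to-hundreds of cliques a condensed summary produces.
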