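# trntopo

Topological analysis of prokaryotic transcriptional regulatory networks
(TRNs) under data incompleteness.

Curated TRNs — directed graphs of regulator→target transcriptional
interactions, optionally signed (+1 activation / −1 inhibition) and
annotated with the experimental evidence behind each link — are
incomplete and heterogeneously characterized. This package provides a
tested, reproducible pipeline for the three analyses where that
incompleteness bites hardest:

1. **Mesoscale.** Signed, directed modularity
   `Q = w⁺/(w⁺+w⁻)·Q⁺ − w⁻/(w⁺+w⁻)·Q⁻` optimized over a grid of
   resolutions via uniform self-loop rescaling `A_r = A + I·r`, with
   plateau detection (ranges of `r` with a stable module count `N_c`)
   and partition comparison against functional classifications using
   the Asymmetric Wallace index
   `AW(A,B) = Σ_αβ M_αβ(M_αβ−1) / Σ_α M_α·(M_α·−1)` — the probability
   that a pair co-clustered in A stays co-clustered in B. The DS / DU /
   UU projections (directed-signed, directed-unsigned,
   undirected-unsigned) of one network quantify how much mesoscale
   structure is lost when link attributes are dropped.

2. **Motifs.** Exact census of the 13 connected 3-node triad classes,
   Z-scores `Z_h = (n_h − ⟨n_rand,h⟩)/σ_rand,h` against a switching
   null ensemble that preserves every node's single-edge and
   mutual-dyad degrees, and the unit-normalized triad significance
   profile (TSP). When a network has no feedback loops (mutual dyads)
   the null ensemble cannot produce any either, so the eight
   mutual-containing triad classes have **undefined** Z-scores — the
   mechanism by which sparse early datasets distorted network-family
   comparisons — and the package reports them as undefined rather than
   as numbers.

3. **Evidence bias.** A link u→w paralleled by a sign-coherent two-link
   cascade u→v→w is *topologically suspicious* (a candidate spurious
   indirect inference); links backed by both a binding assay (BA) and an
   expression comparison (TELC) are *well-characterized* (WCLs). The
   2×2 contingency table (suspicious × WCL) is tested with a one-sided
   Fisher's exact test, and a correction deletes the largest number `x`
   of poorly characterized suspicious links such that the remaining
   suspicious WCL fraction `a/(a+b−x)` stays at or below the
   network-wide fraction `(a+c)/(a+b+c+d)`, then recomputes the TSP.

A synthetic TRN generator (small regulator fraction, power-law hubs,
compact in-degrees, planted modules / motifs / evidence deficits) plus
ground truth makes every stage testable without downloading any
database. See `docs/methods.md` for models, defaults and limitations.

## Worked example

```python
import trntopo as tt
from trntopo.synth import SyntheticSpec, generate

net, truth = generate(SyntheticSpec(seed=7))
print(net.stats())

suspicious = tt.find_suspicious(net)
table = tt.contingency(net, suspicious)
print(len(suspicious), table.wcl_fraction_suspicious, table.wcl_fraction_rest)
print(tt.fisher_one_sided(table).p_value)

x = tt.correction_count(table)
result = tt.apply_correction(net, x, seed=7, R=80, n_switch_per_edge=10)
print(x, result.z_before[3], result.z_after[3])
```

prints (formatted):

```
N=1000 L=3432 SL=0 regulators=80 feedback_loops=45
suspicious links: 1311
WCL fraction: 0.168 (suspicious) vs 0.241 (rest)
one-sided Fisher p = 1.71e-07
correction count x = 278
Z_cascade -4.80 -> -2.96
Z_ffl     +5.21 -> +3.23
TSP correlation before/after = 0.968
```

Reading: the generator planted a WCL deficit inside the suspicious
set, the one-sided Fisher test detects it decisively, and deleting the
278 poorly characterized suspicious links that pair the WCL fraction
back to background shrinks the cascade/FFL Z-scores while leaving the
normalized significance profile nearly unchanged (correlation 0.97) —
the same qualitative behavior reported for the curated E. coli,
B. subtilis and M. tuberculosis networks.

The command line mirrors the library:

```sh
trntopo synth --seed 7 --out run7          # network.tsv + nodes.tsv + ground_truth.json
trntopo bias run7/network.tsv --nodes run7/nodes.tsv --exclude-sigma --out run7
trntopo tsp run7/network.tsv -R 200 --out run7
trntopo mesoscale run7/network.tsv --level DS --r-min -1 --r-max 4 --out run7
trntopo catalog                            # the 13 triad classes as edge lists
trntopo defaults                           # default config + synthetic spec
```

Input format is a plain TSV edge list (`source target sign evidence
role_source`, sign tokens `+`/`-`/`?`, evidence as comma-separated
`tag:BA`/`tag:TELC` pairs) with an optional node-annotation TSV;
real curated datasets can be used after conversion to this format.

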