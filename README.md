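# netbackbone

Extract the *backbone* — a sparse unweighted (optionally signed) subnetwork
containing only the statistically or structurally important edges — from a
weighted network, a bipartite network (via its projection), or an
unweighted network.

## Models

| Input type | Function | Models |
|---|---|---|
| weighted network | `backbone_from_weighted` | `global`, `disparity` (default), `lans`, `mlf` |
| bipartite incidence | `backbone_from_projection` | `sdsm` (default), `fdsm`, `fixedrow`, `fixedcol`, `fixedfill` |
| unweighted network | `backbone_from_unweighted` | `lspar` (default), `gspar`, `degree`, `skeleton`, `simmelian`, `quadrilateral`, `jaccard`, `meetmin`, `geometric`, `hyper`, or custom `escore`/`normalize`/`filter`/`umst` pipelines |

The `backbone()` wrapper auto-detects the input type and applies the
default model (SDSM at α=0.05 for bipartite inputs, disparity filter at
α=0.05 for weighted networks, local sparsification with parameter 0.5 for
unweighted networks). Statistical models support multiple-test correction
(`mtc` ∈ {none, bonferroni, holm, bh, by}; `fdr` is an alias for `bh`) and
signed backbones (`signed=True`: significantly strong edges are retained
as +1, significantly weak edges as −1, at α/2 per tail).

Standalone utilities: `bicm_fit` (bipartite configuration model),
`fastball_sample` (fixed-marginal matrix randomization by curveball
trades), and `poisson_binomial_tail` (exact DP tails up to 8192 terms,
refined normal approximation beyond).

## Library quick start

```python
import netbackbone as nb

B = nb.read_network("sponsorship.tsv", bipartite=True)   # agents x artifacts
res = nb.backbone(B, alpha=0.05)                         # SDSM backbone
print(res.narrative)                                     # e.g. "... reduced the number of edges by 82.93%"
nb.write_backbone(res, "backbone.tsv")
```

## Command line

```bash
netbackbone auto -i network.tsv -o backbone.tsv
netbackbone weighted   -i net.tsv -o bb.tsv --model disparity --alpha 0.05
netbackbone projection -i incidence.tsv -o bb.tsv --model fdsm --trials 1000 --seed 1
netbackbone unweighted -i net.tsv -o bb.tsv --model lspar --parameter 0.5
netbackbone unweighted -i net.tsv -o bb.tsv --escore jaccard --normalize rank --filter degree --parameter 0.5
netbackbone simulate --kind sbm --seed 1 -o sbm.tsv
```

Inputs: whitespace/TAB edge lists (optional third weight column, `#`
comments), dense adjacency text, Matrix Market (`.mtx`), or GraphML.
Bipartite inputs are agents × artifacts incidence matrices or two-column
agent–artifact edge lists (`--bipartite` for `auto`).

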