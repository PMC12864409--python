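# panelnet

Symptom-network analysis for two-wave panel data: regularized partial-
correlation networks per wave, node centrality with bootstrap accuracy and
stability checks, a cross-lagged panel network (CLPN) between waves, and
paired descriptive statistics — plus a seeded synthetic-data generator with
known ground truth for validating the whole pipeline.

The default instrument panel has ten nodes: three craving subscales (D1–D3),
three compulsive-seeking subscales (O1–O3), three impulsivity subscales
(B1–B3), and stop-signal reaction time (SSRT).

## Quickstart

```python
import panelnet as pn

# a 361-subject two-wave panel with 209 completers, fully seeded
truth = pn.make_default_truth(1)
panel = pn.simulate_panel(truth)
print(panel.n_subjects, int(panel.observed[:, 1].sum()))
# 361 209

# baseline network: glasso path + EBIC (gamma = 0.5), refit edge weights
net = pn.estimate_network(panel.wave_frame("T0"))
print(net.edge_count(), round(net.lambda_selected, 4))
# 8 0.1989
print(net.edge_list().head(3).to_string(index=False))
# node_a node_b   weight
#     D1     D2 0.365291
#     D1     O2 0.294598
#     D3     O3 0.294921

# centrality (strength and one-step expected influence)
tab = pn.centrality_table(net)
print(tab.loc[tab["expected_influence"].idxmax(), "node"])
# O1

# cross-lagged panel network on the 209 completers (node-wise LASSO, 10-fold CV)
model = pn.fit_clpn(panel, seed=13)
cl = pn.reported_edges(model).query("type == 'cross_lagged'")
print(len(cl))
# 6
print(cl.head(3).to_string(index=False))
# from to   weight         type  sign
#   D2 D1 0.177088 cross_lagged     1
#   O1 B1 0.168587 cross_lagged     1
#   O2 O1 0.138585 cross_lagged     1

# paired T0-vs-T1 comparison with automatic test selection
comp = pn.compare_waves(panel).set_index("node")
print(comp.loc["SSRT", ["test", "p_value"]].to_string())
# test       paired_t
# p_value    0.261344
```

Resampling diagnostics:

```python
boot = pn.bootstrap_edges(panel.wave_frame("T0"), B=1000, seed=11)   # edge CIs
stab = pn.network_stability(panel.wave_frame("T0"), seed=12)          # CS coefficients
```

## Command line

Every stage is a subcommand; `run` executes the full pipeline from a YAML
config and writes CSV/JSON artifacts plus a manifest:

```sh
panelnet simulate --seed 1 --out panel.csv
panelnet estimate --panel panel.csv --wave T0 --out network.json
panelnet run --config config.yaml        # describe -> screen -> estimate ->
                                         # centrality -> bootstrap -> stability ->
                                         # compare -> clpn
```

Identical configs reproduce byte-identical numeric outputs; every random
stage carries an explicit seed. See `panelnet --help` for all subcommands.

## Documentation

Statistical conventions (EBIC selection with refit likelihood, CS-coefficient
definition, Wilcoxon zero/tie handling, the synthetic ground truth, etc.) are
documented in [docs/methods.md](docs/methods.md).

## Testing

```sh
pytest -q          # unit + property tests, then the acceptance suite
```

The acceptance tests validate the glasso solver against an independent convex
oracle, recover the simulation ground truth (structure, bootstrap coverage,
CLPN coefficients), and check end-to-end pipeline determinism. The full suite
takes roughly 15 minutes on one CPU; everything except `tests/test_acceptance.py`
finishes in about a minute.
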