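# gmcskit

Enumeration of **genetic minimal cut sets** (gMCSs) in constraint-based
metabolic models: essential genes, synthetic-lethal gene sets, and
growth-coupling interventions.

Instead of mixed-integer programming, the method works with a small
*representative* subset of the target flux region: reaction-level cut sets
are derived from gene-protein rules (DNF→CNF conversion via minimal
hitting sets), mode-level families are combined with an incremental Berge
fold under a cardinality cap, and each candidate gene set is confirmed or
refuted with a single LP feasibility check — a refuting flux vector
(witness mode) joins the representative subset and sharpens the next round
of candidates.

## Layout

| module | contents |
| --- | --- |
| `gmcskit.gpr` | GPR parsing, DNF/CNF conversion, reaction-level gMCS families |
| `gmcskit.hitting` | modes, generalized minimal hitting sets (bitmask Berge engine) |
| `gmcskit.model_io` | SBML / COBRA-JSON reading (via cobrapy), media, toy fixture, catalog output |
| `gmcskit.target` | target regions `{v : S·v=0, l≤v≤u, A·v≥b}`, LP knockout feasibility (scipy HiGHS), witness oracles, intervention classification |
| `gmcskit.representative` | the enumeration driver and the gMCS catalog |
| `gmcskit.cli` | `gmcskit` command line |

## CLI

```bash
# worked ten-reaction example (five gMCSs)
gmcskit toy-demo

# synthetic lethality: all gMCSs up to length 4
gmcskit lethality --model iML1515.json --k-max 4 -p 0.01 --out results/iml1515

# growth coupling: ethanol in anaerobic iJO1366
gmcskit couple --model iJO1366.xml --close EX_o2_e --product EX_etoh_e \
    --k-max 4 --out results/ijo1366_etoh
```

Each run writes `<out>.tsv` and `<out>.json` (one record per gMCS:
cardinality, genes, target, classification) plus `<out>.meta.json`
(solver, tolerances, model checksum, per-phase statistics).  Catalog files
are byte-identical across reruns of the same configuration.  Options can
also come from a TOML file via `--config` (explicit flags win).  Exit
codes: 0 success, 2 configuration error, 3 solver failure.

## Python API sketch

```python
from gmcskit import (read_model, apply_medium, build_coupling_target,
                     LPOracle, compute_gmcs, classify_intervention)

model = apply_medium(read_model("iJO1366.xml"), closed_exchanges=["EX_o2_e"])
target = build_coupling_target(model, "EX_etoh_e", p=0.01)
catalog = compute_gmcs(LPOracle(target, k=4), k_max=4)
for G in catalog:
    print(sorted(G), classify_intervention(target, G))
```
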