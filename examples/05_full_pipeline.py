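"""Run the whole analysis from files, the way a real study would.

Writes a synthetic study's input CSVs to disk, then executes
reduce -> aggregate -> trees -> signal -> compare -> regressions from a
RunConfig and prints the highlights of the machine-readable report.
"""

import tempfile
from pathlib import Path

from chemosignal.pipeline import RunConfig, run_full_analysis
from chemosignal.simulate import SimulationConfig, simulate_study

workdir = Path(tempfile.mkdtemp(prefix="chemosignal_"))
study = simulate_study(SimulationConfig(seed=3))
paths = study.write_dir(workdir / "inputs")

report = run_full_analysis(RunConfig(
    concentrations=paths["concentrations"],
    compound_flags=paths["compound_flags"],
    feeding=paths["feeding"],
    genetic=paths["genetic_distances"],
    reference_species=study.reference_species,
    n_perm=999,
    compare_iterations=1000,
    bootstrap=100,
    seed=0,
    out_dir=workdir / "out",
))

print(f"compounds: {report['compounds']['n_detected']} detected, "
      f"{report['compounds']['n_retained']} retained")
print(f"total-GS ANOVA: F = {report['total_gs']['anova']['F']:.2f}, "
      f"p = {report['total_gs']['anova']['p']:.2g}")
for insect, entry in report["insects"].items():
    print(f"\n{insect}:")
    for tree_id, sig in entry["signal"].items():
        print(f"  K on {tree_id:14s} = {sig['K']:5.2f}  (p = {sig['p']:.4f})")
    cmp_all = entry["compare"]["chemical_all_vs_genetic"]
    print(f"  Delta-K (all-leaf dendrogram vs phylogram) = {cmp_all['delta']:.2f}, "
          f"CI [{cmp_all['ci95'][0]:.2f}, {cmp_all['ci95'][1]:.2f}]")
print(f"\nfull report: {workdir / 'out' / 'report.json'}")
print()
print("The specialist's K is clearly higher on the chemical dendrograms than")
print("on the genetic phylogram, with small permutation p-values; the weakly")
print("coupled generalist shows a milder version of the same pattern whose")
print("permutation tests stay non-significant.")
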