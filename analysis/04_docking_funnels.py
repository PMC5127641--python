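#!/usr/bin/env python
"""Post-process docking score tables into funnel statistics.

For an on-target pair the local (near the bound pose) docking runs score
well below the global-surface runs — a funnel; for an off-target pair the
two distributions overlap. The script generates both cases, computes the
mean of the 100 lowest-scoring configurations per run class, and tabulates
absolute (local minimum) and relative (local minus global) binding energy.
"""

from pathlib import Path

import pandas as pd

from specprofiler import structure, synth

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20260930

CASES = {
    # (local mean ddG, global mean ddG): on-target shows a deep funnel
    "on_target": (-32.0, -15.0),
    "off_target": (-17.0, -15.0),
}


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = []
    for i, (case, (local_mean, global_mean)) in enumerate(CASES.items()):
        records, _ = synth.generate_funnel_table(
            local_mean=local_mean, global_mean=global_mean,
            n_local=2000, n_global=2000, seed=SEED + i)
        stats = structure.funnel_stats(records, k=100)
        rows.append({"case": case,
                     "absolute_binding_energy": stats.absolute_binding_energy,
                     "relative_binding_energy": stats.relative_binding_energy,
                     "n_local": stats.n_local_used,
                     "n_global": stats.n_global_used})
        print(f"{case}: local minimum {stats.local_minimum:.1f}, global "
              f"minimum {stats.global_minimum:.1f}, relative "
              f"{stats.relative_binding_energy:.1f}")
    table = pd.DataFrame(rows).set_index("case")
    table.to_csv(OUT / "funnel_stats.tsv", sep="\t")
    gap = (table.loc["off_target", "relative_binding_energy"]
           - table.loc["on_target", "relative_binding_energy"])
    print(f"the on-target funnel is {gap:.1f} energy units deeper in relative "
          f"binding energy than the off-target case")
    print(f"wrote {OUT/'funnel_stats.tsv'}")


if __name__ == "__main__":
    main()
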