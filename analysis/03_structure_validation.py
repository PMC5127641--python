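#!/usr/bin/env python
"""Structural validation on synthetic helix-bundle complexes.

Checks the three structural comparisons the crystallographic analysis
relies on: (1) target-aligned partner RMSD between a "design model" and a
rigidly perturbed "crystal structure" of the same complex, (2) buried
interface area of the complex and its expansion relative to a smaller
reference interface, (3) lysine cross-link mapping with reagent-support
summary.
"""

from dataclasses import replace
from pathlib import Path

import numpy as np

from specprofiler import structure, synth
from specprofiler.structure import StructureModel

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20260930


def two_chain_complex(separation: float, seed: int) -> StructureModel:
    target, _, _ = synth.generate_helix_bundle(n_helices=2, residues_per_helix=16,
                                               seed=seed)
    inhibitor, _, _ = synth.generate_helix_bundle(n_helices=3,
                                                  residues_per_helix=12,
                                                  seed=seed + 1)
    moved = structure.transform_model(inhibitor, np.eye(3),
                                      np.array([separation, 0.0, 0.0]))
    return StructureModel(chains={"T": target.chains["A"],
                                  "I": moved.chains["A"]})


def main() -> None:
    OUT.mkdir(exist_ok=True)

    # 1. design model vs "crystal": rigid displacement of the inhibitor only
    crystal = two_chain_complex(separation=11.0, seed=SEED)
    shift = np.array([1.2, 0.9, 0.6])
    design = StructureModel(chains={
        "T": crystal.chains["T"],
        "I": structure.transform_model(
            StructureModel(chains={"I": crystal.chains["I"]}),
            np.eye(3), shift).chains["I"]})
    rmsd = structure.aligned_partner_rmsd(design, crystal, ("T", "T"), ("I", "I"))
    print(f"target-aligned inhibitor RMSD {rmsd:.2f} A "
          f"(planted displacement {np.linalg.norm(shift):.2f} A)")

    # 2. buried surface area and interface expansion
    bsa_big = structure.buried_surface_area(crystal, ["T"], ["I"], n_points=480)
    smaller = two_chain_complex(separation=14.0, seed=SEED)
    bsa_small = structure.buried_surface_area(smaller, ["T"], ["I"], n_points=480)
    print(f"complex buries {bsa_big:.0f} A^2 (two-sided); the closer pose "
          f"expands the interface by {bsa_big - bsa_small:.0f} A^2 over the "
          f"distant one ({bsa_small:.0f} A^2)")

    # 3. cross-link mapping with planted true/false links
    bundle, _, _ = synth.generate_helix_bundle(n_helices=3, residues_per_helix=30,
                                               seed=SEED + 7)
    links, ledger = synth.generate_crosslink_set(bundle, n_true=14, n_false=6,
                                                 seed=SEED + 8)
    mapped = structure.map_crosslinks(bundle, links)
    n_sat = sum(m.satisfied for m in mapped)
    print(f"{n_sat} of {len(mapped)} cross-links satisfied "
          f"({sum(ledger.manifest['is_true'])} planted within their limits)")
    summary = structure.crosslink_support_summary(mapped)
    print("by reagent support:")
    print(summary.to_string())
    structure.write_crosslink_tsv(mapped, OUT / "crosslinks_mapped.tsv")
    summary.to_csv(OUT / "crosslink_support.tsv", sep="\t")
    print(f"wrote {OUT/'crosslinks_mapped.tsv'} and {OUT/'crosslink_support.tsv'}")


if __name__ == "__main__":
    main()
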