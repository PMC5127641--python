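"""Synthetic-data generators with ground-truth ledgers.

Every input class the analysis modules consume can be generated here with
known ground truth: multinomial sequencing counts of an SSM library before
and after a fitness-dependent selection, noisy 1:1 binding traces, ideal
helix-bundle coordinates under rigid perturbation, cross-link lists with
planted true/false links, and docking score tables with funnel structure.
Each generator takes an explicit seed, uses one private RNG, and returns a
:class:`GeneratorLedger` recording the planted parameters, so expected
downstream results are computable without re-running the generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bli import KineticTrace, model_association, model_dissociation
from .ssm import AMINO_ACIDS, COLUMNS, STOP, VariantCountTable, _empty_counts
from .structure import Atom, CrossLinkRecord, Residue, StructureModel

CODON_OF = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCG", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT", "*": "TAA",
}


@dataclass
class GeneratorLedger:
    """What a generator planted, sufficient to predict downstream output."""

    seed: int
    params: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# SSM library


def default_fitness(reference: str, rng: np.random.Generator,
                    substitution_sd: float = 2.0,
                    stop_fitness: float = -5.0) -> dict:
    """Random fitness landscape: substitutions ~ N(0, sd), stops strongly
    deleterious, wild type at 0 by construction."""
    fitness = {}
    for pos, wt in enumerate(reference, start=1):
        for aa in COLUMNS:
            if aa == wt:
                continue
            fitness[(pos, aa)] = (stop_fitness if aa == STOP
                                  else float(rng.normal(0.0, substitution_sd)))
    return fitness


def generate_ssm_experiment(reference: str, fitness: dict | None = None,
                            depth: int = 100_000, selection_strength: float = 1.0,
                            seed: int = 0, naive_dispersion: float = 0.3,
                            wt_weight: float = 20.0):
    """Simulate naive and sorted pools of a single-mutant SSM library.

    The naive pool is near-uniform over all single substitutions (plus the
    wild type, weighted like ``wt_weight`` variants), with log-normal
    abundance noise of scale ``naive_dispersion``. Each variant survives
    the sort with probability logistic(selection_strength * fitness); the
    wild type has fitness 0. Counts in both pools are multinomial draws of
    ``depth`` reads.

    Returns (naive, sorted, ledger); the ledger stores the fitness map.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    if fitness is None:
        fitness = default_fitness(reference, rng)
    variants = sorted(fitness)  # (position, aa), aa != wild type
    if any(aa == reference[pos - 1] for pos, aa in variants):
        raise ValueError("fitness map must not contain wild-type cells")

    weights = np.ones(len(variants) + 1)  # last slot = wild type
    weights[-1] = wt_weight
    weights *= np.exp(rng.normal(0.0, naive_dispersion, size=weights.size))
    p_naive = weights / weights.sum()

    f = np.array([fitness[v] for v in variants] + [0.0])
    survival = 1.0 / (1.0 + np.exp(-selection_strength * f))
    if not np.all((survival >= 0) & (survival <= 1)):
        raise ValueError("invalid survival probabilities")
    p_sorted = p_naive * survival
    p_sorted /= p_sorted.sum()

    tables = []
    for label, p in (("naive", p_naive), ("sorted", p_sorted)):
        draws = rng.multinomial(depth, p)
        counts = _empty_counts(len(reference))
        for (pos, aa), c in zip(variants, draws[:-1]):
            counts.loc[pos, aa] = int(c)
        tables.append(VariantCountTable(
            reference=reference, counts=counts, pool_label=label,
            wildtype_count=int(draws[-1]),
            sort_metadata=f"synthetic selection, strength {selection_strength}"))
    ledger = GeneratorLedger(
        seed=seed,
        params={"depth": depth, "selection_strength": selection_strength,
                "naive_dispersion": naive_dispersion, "wt_weight": wt_weight},
        manifest={"fitness": fitness})
    return tables[0], tables[1], ledger


def generate_variant_reads(reference: str, substitutions: list | None = None,
                           n_reads: int = 100, seed: int = 0,
                           wt_fraction: float = 0.2):
    """Reads of the coding window, each wild type or one planted substitution.

    Returns (reads, reference_cds, ledger); the ledger manifest lists the
    planted (position, amino_acid) multiset so a variant counter can be
    checked cell for cell.
    """
    rng = np.random.default_rng(seed)
    wt_codons = [CODON_OF[aa] for aa in reference]
    reads, planted = [], []
    n_wt = 0
    for _ in range(n_reads):
        if substitutions is None:
            make_wt = rng.random() < wt_fraction
        else:
            make_wt = False
        if substitutions is not None:
            pos, aa = substitutions[len(planted) % len(substitutions)]
        elif not make_wt:
            pos = int(rng.integers(1, len(reference) + 1))
            choices = [a for a in COLUMNS if a != reference[pos - 1]]
            aa = choices[int(rng.integers(len(choices)))]
        if make_wt:
            reads.append("".join(wt_codons))
            n_wt += 1
        else:
            codons = list(wt_codons)
            codons[pos - 1] = CODON_OF[aa]
            reads.append("".join(codons))
            planted.append((pos, aa))
    ledger = GeneratorLedger(seed=seed, params={"n_reads": n_reads},
                             manifest={"planted": planted, "wildtype_reads": n_wt})
    return reads, "".join(wt_codons), ledger


# ---------------------------------------------------------------------------
# BLI traces


def generate_bli_dataset(pairs: list, concentrations, noise_sd: float = 0.0,
                         seed: int = 0, t_assoc: float = 300.0,
                         t_dissoc: float = 600.0, n_time: int = 120):
    """Association/dissociation traces from the 1:1 model plus iid noise.

    ``pairs`` lists (pair_id, kon, koff, rmax). Each pair is titrated at
    every concentration; dissociation starts from the response reached at
    the end of the association phase. Returns (traces, ledger).
    """
    rng = np.random.default_rng(seed)
    traces = []
    truth = {}
    t_a = np.linspace(0.0, t_assoc, n_time)[1:]  # association starts near 0 signal
    t_a = np.insert(t_a, 0, 0.0)
    t_d = np.linspace(0.0, t_dissoc, n_time)
    for pair_id, kon, koff, rmax in pairs:
        if kon <= 0 or koff <= 0 or rmax <= 0:
            raise ValueError("kinetic parameters must be positive")
        truth[tuple(pair_id)] = {"kon": kon, "koff": koff, "rmax": rmax,
                                 "kd": koff / kon}
        for conc in concentrations:
            assoc = model_association(kon, koff, rmax, conc, t_a)
            r0 = float(assoc[-1])
            dissoc = model_dissociation(r0, koff, t_d)
            for phase, t, y in (("association", t_a, assoc),
                                ("dissociation", t_d, dissoc)):
                noisy = y + rng.normal(0.0, noise_sd, size=y.size) if noise_sd else y
                traces.append(KineticTrace(time=t, signal=noisy,
                                           concentration=float(conc), phase=phase,
                                           pair_id=tuple(pair_id)))
    ledger = GeneratorLedger(
        seed=seed,
        params={"concentrations": list(map(float, concentrations)),
                "noise_sd": noise_sd, "t_assoc": t_assoc, "t_dissoc": t_dissoc},
        manifest={"kinetics": truth})
    return traces, ledger


# Synthetic specificity panel: one inhibitor per pro-survival homolog, with
# high-picomolar-to-low-nanomolar on-target affinity, one measurable
# off-target several hundred fold weaker, and the remaining homologs showing
# no detectable binding up to the censoring concentration.
PANEL = {
    "aBCL2": {"on_target": "Bcl-2", "kd_on": 2e-10,
              "weak_off": ("Mcl-1", 500.0)},
    "aBCLXL": {"on_target": "Bcl-xL", "kd_on": 5e-10,
               "weak_off": ("Bcl-w", 800.0)},
    "aBCLW": {"on_target": "Bcl-w", "kd_on": 1e-9,
              "weak_off": ("Bcl-xL", 400.0)},
    "aMCL1": {"on_target": "Mcl-1", "kd_on": 5e-11,
              "weak_off": ("Bfl-1", 2000.0)},
    "aBFL1": {"on_target": "Bfl-1", "kd_on": 5e-10,
              "weak_off": ("Mcl-1", 600.0)},
    "aBCLB": {"on_target": "Bcl-B", "kd_on": 1.5e-9,
              "weak_off": ("Bcl-2", 350.0)},
}

PANEL_KON = 1e6          # M^-1 s^-1, typical protein-protein association
PANEL_CENSOR_CONC = 1e-6  # molar; top concentration for no-binding pairs


def generate_specificity_panel(seed: int = 0, noise_sd: float = 0.01,
                               rmax: float = 1.0, panel: dict | None = None):
    """BLI titrations for a six-inhibitor / six-homolog specificity study.

    Each inhibitor is titrated against all six homologs: the on-target pair
    and one measurable weak off-target get 1:1-model traces at three
    concentrations bracketing their KD; the other homologs yield pure-noise
    traces at concentrations up to the censoring bound. Returns
    (traces_by_inhibitor, ledger); the ledger stores every true KD and the
    true minimum fold-specificity per inhibitor.
    """
    from .bli import HOMOLOGS

    panel = panel or PANEL
    rng = np.random.default_rng(seed)
    datasets, truth = {}, {}
    for i, (inhibitor, cfg) in enumerate(sorted(panel.items())):
        kd_by_homolog, traces = {}, []
        for homolog in HOMOLOGS:
            if homolog == cfg["on_target"]:
                kd = cfg["kd_on"]
            elif homolog == cfg["weak_off"][0]:
                kd = cfg["kd_on"] * cfg["weak_off"][1]
            else:
                kd = None  # no detectable binding
            kd_by_homolog[homolog] = kd
            if kd is not None:
                concs = [kd / 3, kd, 3 * kd]
                koff = PANEL_KON * kd
                # phase lengths track the kinetics so slow binders still
                # approach equilibrium and show measurable dissociation
                sub, _ = generate_bli_dataset(
                    [((inhibitor, homolog), PANEL_KON, koff, rmax)],
                    concs, noise_sd=noise_sd,
                    seed=int(rng.integers(2 ** 31)), n_time=60,
                    t_assoc=2.0 / koff, t_dissoc=3.0 / koff)
                traces.extend(sub)
            else:
                t = np.linspace(0.0, 300.0, 60)
                for conc in (PANEL_CENSOR_CONC / 10, PANEL_CENSOR_CONC):
                    for phase in ("association", "dissociation"):
                        traces.append(KineticTrace(
                            time=t, signal=rng.normal(0.0, noise_sd, t.size),
                            concentration=conc, phase=phase,
                            pair_id=(inhibitor, homolog)))
        measurable = {h: k for h, k in kd_by_homolog.items()
                      if k is not None and h != cfg["on_target"]}
        true_fold = min(min(measurable.values()) / cfg["kd_on"],
                        PANEL_CENSOR_CONC / cfg["kd_on"])
        truth[inhibitor] = {"on_target": cfg["on_target"],
                            "kd": kd_by_homolog, "min_fold": true_fold}
        datasets[inhibitor] = traces
    ledger = GeneratorLedger(seed=seed,
                             params={"noise_sd": noise_sd, "rmax": rmax,
                                     "kon": PANEL_KON,
                                     "censor_conc": PANEL_CENSOR_CONC},
                             manifest={"panel": truth})
    return datasets, ledger


# ---------------------------------------------------------------------------
# helix bundles

HELIX_RISE = 1.5       # A per residue
HELIX_TWIST = 100.0    # degrees per residue
HELIX_RADIUS = 2.3     # A, Calpha radius about the helix axis


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix, det fixed)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def generate_helix_bundle(n_helices: int = 3, residues_per_helix: int = 24,
                          rotation_deg: float = 0.0, translation: float = 0.0,
                          jitter_sd: float = 0.0, seed: int = 0,
                          axis_spacing: float = 10.0, lysine_every: int = 5):
    """Ideal alpha-helix bundle and a rigidly perturbed copy.

    Helices run antiparallel along z on a circle of axes ``axis_spacing``
    apart; each residue gets a Calpha and a dummy CB heavy atom. The
    perturbed copy is rotated by ``rotation_deg`` about a random axis,
    translated by a random vector of length ``translation``, then jittered
    per coordinate with sd ``jitter_sd``. Every ``lysine_every``-th residue
    is a lysine (cross-link anchor); the rest are alanine.

    Returns (reference, perturbed, ledger); the ledger stores the exact
    rigid transform.
    """
    if n_helices < 1 or residues_per_helix < 1:
        raise ValueError("bundle sizes must be at least 1")
    rng = np.random.default_rng(seed)

    residues = []
    resnum = 0
    ring_r = axis_spacing / (2 * np.sin(np.pi / n_helices)) if n_helices > 1 else 0.0
    for h in range(n_helices):
        ang = 2 * np.pi * h / n_helices
        axis_xy = ring_r * np.array([np.cos(ang), np.sin(ang)])
        direction = 1 if h % 2 == 0 else -1
        for i in range(residues_per_helix):
            resnum += 1
            phase = np.deg2rad(HELIX_TWIST * i)
            ca = np.array([
                axis_xy[0] + HELIX_RADIUS * np.cos(phase),
                axis_xy[1] + HELIX_RADIUS * np.sin(phase),
                direction * HELIX_RISE * i,
            ])
            radial = np.array([np.cos(phase), np.sin(phase), 0.0])
            cb = ca + 1.5 * radial
            name = "LYS" if resnum % lysine_every == 0 else "ALA"
            residues.append(Residue(
                number=resnum, icode="", name=name,
                atoms={"CA": Atom("CA", "C", ca), "CB": Atom("CB", "C", cb)}))
    reference = StructureModel(chains={"A": residues},
                               metadata={"source": "synthetic helix bundle"})

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    theta = np.deg2rad(rotation_deg)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    rot = np.eye(3) + np.sin(theta) * k + (1 - np.cos(theta)) * (k @ k)
    tvec = rng.normal(size=3)
    tvec = translation * tvec / np.linalg.norm(tvec) if translation else np.zeros(3)

    from .structure import transform_model

    perturbed = transform_model(reference, rot, tvec)
    if jitter_sd:
        for res in perturbed.chains["A"]:
            for atom in res.atoms.values():
                atom.xyz = atom.xyz + rng.normal(0.0, jitter_sd, size=3)
    ledger = GeneratorLedger(
        seed=seed,
        params={"n_helices": n_helices, "residues_per_helix": residues_per_helix,
                "rotation_deg": rotation_deg, "translation": translation,
                "jitter_sd": jitter_sd},
        manifest={"rotation": rot, "translation": tvec})
    return reference, perturbed, ledger


# ---------------------------------------------------------------------------
# cross-link sets

_REAGENT_CYCLE = [frozenset({"DSS", "BS3", "DSG"}), frozenset({"DSS", "BS3"}),
                  frozenset({"DSS"}), frozenset({"BS3", "DSG"}),
                  frozenset({"DSG"})]


def generate_crosslink_set(model: StructureModel, n_true: int, n_false: int,
                           seed: int = 0, chain: str = "A"):
    """Plant satisfied and violated lysine cross-links on a model.

    Reagent support cycles through all support levels; each link's own
    distance limit (most permissive reagent) decides the true/false
    sampling window. Returns (records, ledger); the ledger manifest labels
    every link true (within limit) or false (beyond it).
    """
    from .structure import REAGENT_LIMIT

    rng = np.random.default_rng(seed)
    lysines = [r for r in model.residues(chain)
               if r.name == "LYS" and r.ca is not None]
    if len(lysines) < 2:
        raise ValueError("model needs at least two lysine residues")
    pairs = [(a, b) for i, a in enumerate(lysines) for b in lysines[i + 1:]]
    rng.shuffle(pairs)

    records, labels = [], []
    cycle = 0
    for want_true, count in ((True, n_true), (False, n_false)):
        made = 0
        for a, b in list(pairs):
            if made == count:
                break
            reagents = _REAGENT_CYCLE[cycle % len(_REAGENT_CYCLE)]
            limit = max(REAGENT_LIMIT[r] for r in reagents)
            dist = float(np.linalg.norm(a.ca - b.ca))
            if (dist <= limit) != want_true:
                continue
            records.append(CrossLinkRecord(chain_a=chain, res_a=a.number,
                                           chain_b=chain, res_b=b.number,
                                           reagents=reagents))
            labels.append(want_true)
            pairs.remove((a, b))
            cycle += 1
            made += 1
        if made < count:
            raise ValueError(
                f"only {made} candidate pairs available for planted "
                f"{'true' if want_true else 'false'} links (wanted {count})")
    ledger = GeneratorLedger(seed=seed,
                             params={"n_true": n_true, "n_false": n_false},
                             manifest={"is_true": labels})
    return records, ledger


# ---------------------------------------------------------------------------
# docking funnels


def generate_funnel_table(local_mean: float = -30.0, global_mean: float = -15.0,
                          score_sd: float = 3.0, n_local: int = 2000,
                          n_global: int = 2000, seed: int = 0,
                          local_rmsd_scale: float = 2.0,
                          global_rmsd_max: float = 40.0) -> tuple[pd.DataFrame, GeneratorLedger]:
    """Score table with funnel structure: low-RMSD local docks score low.

    Local records have RMSD ~ |N(0, scale)| and ddG ~ N(local_mean, sd)
    plus a mild RMSD penalty; global records spread RMSD uniformly with
    ddG ~ N(global_mean, sd). Returns (records, ledger with the configured
    means).
    """
    if n_local < 1 or n_global < 1:
        raise ValueError("need at least one record per class")
    rng = np.random.default_rng(seed)
    local_rmsd = np.abs(rng.normal(0.0, local_rmsd_scale, n_local))
    local_ddg = rng.normal(local_mean, score_sd, n_local) + 0.5 * local_rmsd
    global_rmsd = rng.uniform(0.0, global_rmsd_max, n_global)
    global_ddg = rng.normal(global_mean, score_sd, n_global)
    records = pd.DataFrame({
        "ddg": np.concatenate([local_ddg, global_ddg]),
        "rmsd": np.concatenate([local_rmsd, global_rmsd]),
        "run": ["local"] * n_local + ["global"] * n_global,
    })
    ledger = GeneratorLedger(
        seed=seed,
        params={"n_local": n_local, "n_global": n_global, "score_sd": score_sd},
        manifest={"local_mean": local_mean, "global_mean": global_mean})
    return records, ledger
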