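"""Site-saturation mutagenesis (SSM) enrichment analysis.

A single-mutant library of a designed protein is displayed on yeast,
FACS-sorted for specific binding to a target BCL2 homolog, and the naive
and sorted pools are deep sequenced. The log2 change in each variant's
frequency between the pools (the *enrichment ratio*, or e-ratio) is a
fitness score for affinity/specificity toward the target. This module
counts variants from reads, forms the enrichment matrix, masks cells with
insufficient coverage, centers each position on its 20-amino-acid mean,
and derives the design-accuracy and library-design statistics built on
top of the matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.Seq import Seq

AMINO_ACIDS = list("ACDEFGHIKLMNPQRSTVWY")
STOP = "*"
COLUMNS = AMINO_ACIDS + [STOP]

MASK_OK = "ok"
MASK_INSUFFICIENT = "insufficient_data"


def _empty_counts(length: int) -> pd.DataFrame:
    return pd.DataFrame(
        0, index=pd.RangeIndex(1, length + 1, name="position"), columns=COLUMNS
    )


@dataclass
class VariantCountTable:
    """Read counts of an SSM pool: positions x (20 aa + stop).

    ``counts`` holds substitution counts only; reads identical to the
    reference accumulate in ``wildtype_count`` (one shared tally, since a
    wild-type read is uninformative about which position it "belongs" to).
    Reads carrying more than one substitution, or rejected for frame/length
    problems, are tallied separately and excluded from the matrix.
    """

    reference: str
    counts: pd.DataFrame
    pool_label: str
    wildtype_count: int = 0
    multi_mutant_count: int = 0
    rejected_count: int = 0
    sort_metadata: str = ""

    def __post_init__(self) -> None:
        length = len(self.reference)
        if list(self.counts.columns) != COLUMNS:
            raise ValueError("count columns must be the 20 amino acids plus stop")
        if len(self.counts) != length or self.counts.index[0] != 1:
            raise ValueError("count rows must be positions 1..len(reference)")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.wildtype_count < 0:
            raise ValueError("wildtype count must be non-negative")

    @property
    def length(self) -> int:
        return len(self.reference)

    def matrix(self) -> pd.DataFrame:
        """Counts with every wild-type cell filled by the shared WT tally."""
        mat = self.counts.astype(float).copy()
        for pos, aa in enumerate(self.reference, start=1):
            mat.loc[pos, aa] = self.wildtype_count
        return mat

    def total(self) -> int:
        """Pool size: substitution reads plus wild-type reads."""
        return int(self.counts.to_numpy().sum()) + self.wildtype_count


@dataclass
class EnrichmentTable:
    """Log2 enrichment ratios, positions x (20 aa + stop); NaN where missing."""

    eratio: pd.DataFrame
    mask: pd.Series  # position -> MASK_OK / MASK_INSUFFICIENT
    pseudocount: float
    reference: str
    designed_sequence: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.eratio.columns) != COLUMNS:
            raise ValueError("e-ratio columns must be the 20 amino acids plus stop")
        if len(self.designed_sequence) != len(self.reference):
            raise ValueError("designed sequence length must match reference")

    @property
    def positions(self) -> pd.Index:
        return self.eratio.index

    def ok_positions(self) -> list[int]:
        return [int(p) for p in self.positions if self.mask.loc[p] == MASK_OK]


@dataclass
class PositionStats:
    """Per-position summary of the enrichment landscape.

    ``frame`` columns: designed_aa, mean_eratio, max_eratio, min_eratio,
    designed_eratio, deviation_from_max, deviation_from_mean, argmax_set.
    Positions whose designed residue has no e-ratio are listed in
    ``excluded`` rather than silently dropped.
    """

    frame: pd.DataFrame
    excluded: list[int]


# ---------------------------------------------------------------------------
# variant counting


def count_variants(reads, reference_cds: str, offset: int = 0,
                   pool_label: str = "naive", sort_metadata: str = "") -> VariantCountTable:
    """Tally single-substitution variants from reads of the mutagenized window.

    Parameters
    ----------
    reads : iterable of str / Bio.SeqRecord
        Nucleotide reads covering the mutagenized window in frame.
    reference_cds : str
        Coding sequence of the window (length divisible by 3).
    offset : int
        0-based nucleotide position within each read where the codon of
        protein position 1 starts.

    Reads translating to the reference exactly increment the wild-type
    tally; reads with exactly one amino-acid substitution increment the
    corresponding matrix cell (stop codons count in the stop column);
    reads with several substitutions are tallied in ``multi_mutant_count``;
    reads that are too short, out of frame, or contain ambiguous codons
    are rejected.
    """
    if len(reference_cds) % 3 != 0:
        raise ValueError("reference coding sequence length must be a multiple of 3")
    reference = str(Seq(reference_cds).translate())
    if STOP in reference:
        raise ValueError("reference coding sequence contains an internal stop codon")
    length = len(reference)
    window = 3 * length

    counts = _empty_counts(length)
    wt = multi = rejected = n_reads = 0
    for read in reads:
        n_reads += 1
        seq = str(getattr(read, "seq", read)).upper()
        if len(seq) < offset + window:
            rejected += 1
            continue
        coding = seq[offset:offset + window]
        if any(b not in "ACGT" for b in coding):
            rejected += 1
            continue
        protein = str(Seq(coding).translate())
        diffs = [(i + 1, a) for i, (a, r) in enumerate(zip(protein, reference)) if a != r]
        if not diffs:
            wt += 1
        elif len(diffs) == 1:
            pos, aa = diffs[0]
            counts.loc[pos, aa] += 1
        else:
            multi += 1
    if n_reads == 0:
        raise ValueError("no reads supplied")
    return VariantCountTable(
        reference=reference, counts=counts, pool_label=pool_label,
        wildtype_count=wt, multi_mutant_count=multi, rejected_count=rejected,
        sort_metadata=sort_metadata,
    )


# ---------------------------------------------------------------------------
# enrichment ratios


def enrichment_ratio(naive: VariantCountTable, sorted_pool: VariantCountTable,
                     pseudocount: float = 0.5,
                     designed_sequence: str | None = None) -> EnrichmentTable:
    """Log2 frequency ratio of every variant between sorted and naive pools.

    e(i, a) = log2[ ((c_sorted + p) / (N_sorted + p*V)) /
                    ((c_naive  + p) / (N_naive  + p*V)) ]

    where N is the pool total (substitutions + wild type), V the number of
    matrix cells, and p the additive pseudocount. With p = 0, cells with a
    zero count in either pool are undefined and left missing.
    """
    if naive.reference != sorted_pool.reference:
        raise ValueError("pools must share the reference sequence")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    n_naive, n_sorted = naive.total(), sorted_pool.total()
    if n_naive == 0:
        raise ValueError("naive pool total is zero")
    if n_sorted == 0:
        raise ValueError("sorted pool total is zero")

    c_naive = naive.matrix().to_numpy()
    c_sorted = sorted_pool.matrix().to_numpy()
    n_cells = c_naive.size
    p = float(pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_naive = (c_naive + p) / (n_naive + p * n_cells)
        f_sorted = (c_sorted + p) / (n_sorted + p * n_cells)
        ratio = np.log2(f_sorted / f_naive)
    if p == 0:
        ratio[(c_naive == 0) | (c_sorted == 0)] = np.nan

    eratio = pd.DataFrame(ratio, index=naive.counts.index, columns=COLUMNS)
    mask = pd.Series(MASK_OK, index=eratio.index)
    return EnrichmentTable(
        eratio=eratio, mask=mask, pseudocount=p,
        reference=naive.reference,
        designed_sequence=designed_sequence or naive.reference,
        metadata={
            "formula": "log2 frequency ratio, additive pseudocount (Enrich-style)",
            "pool_totals": {"naive": n_naive, "sorted": n_sorted},
        },
    )


def mask_low_coverage(table: EnrichmentTable, naive: VariantCountTable,
                      min_reads: int = 10) -> EnrichmentTable:
    """Blank cells whose naive count is below ``min_reads``.

    Positions where more than half the 21 cells end up missing are flagged
    ``insufficient_data`` (the gray columns of a landscape heatmap).
    """
    if min_reads < 0:
        raise ValueError("min_reads must be non-negative")
    eratio = table.eratio.copy()
    low = naive.matrix().to_numpy() < min_reads
    eratio.values[low] = np.nan
    missing_frac = eratio.isna().sum(axis=1) / len(COLUMNS)
    mask = pd.Series(
        np.where(missing_frac > 0.5, MASK_INSUFFICIENT, MASK_OK), index=eratio.index
    )
    return replace(table, eratio=eratio, mask=mask)


def positionwise_normalize(table: EnrichmentTable) -> EnrichmentTable:
    """Center each position on its mean over the 20 amino acids.

    The stop column is excluded from the mean but shifted by it, so stop
    e-ratios stay on the same per-position scale. Positions with no
    non-missing amino-acid cell are left missing and flagged.
    """
    eratio = table.eratio.copy()
    mask = table.mask.copy()
    means = eratio[AMINO_ACIDS].mean(axis=1, skipna=True)
    all_missing = means.isna()
    eratio = eratio.sub(means.fillna(0.0), axis=0)
    mask[all_missing] = MASK_INSUFFICIENT
    meta = dict(table.metadata, normalized="per-position mean over 20 aa set to 0")
    return replace(table, eratio=eratio, mask=mask, metadata=meta)


def deviation_stats(table: EnrichmentTable) -> PositionStats:
    """Design-accuracy statistics per position.

    For each position with usable data, report the max / mean / min e-ratio
    over the 20 amino acids (stop excluded), the designed residue's e-ratio,
    the deviation from the per-position maximum (max - designed, always
    >= 0 since the designed residue is one of the 20), and the deviation
    from the per-position mean (designed - mean). Positions whose designed
    residue has no e-ratio, or flagged for insufficient data, are excluded.
    """
    rows, excluded = [], []
    aa_block = table.eratio[AMINO_ACIDS]
    for pos in table.positions:
        designed_aa = table.designed_sequence[pos - 1]
        row = aa_block.loc[pos]
        designed_val = row.get(designed_aa, np.nan)
        if table.mask.loc[pos] != MASK_OK or pd.isna(designed_val) or row.isna().all():
            excluded.append(int(pos))
            continue
        vmax, vmean, vmin = row.max(), row.mean(), row.min()
        argmax = frozenset(row.index[row == vmax])
        rows.append({
            "position": int(pos), "designed_aa": designed_aa,
            "mean_eratio": vmean, "max_eratio": vmax, "min_eratio": vmin,
            "designed_eratio": designed_val,
            "deviation_from_max": vmax - designed_val,
            "deviation_from_mean": designed_val - vmean,
            "argmax_set": argmax,
        })
    frame = pd.DataFrame(rows).set_index("position") if rows else pd.DataFrame()
    return PositionStats(frame=frame, excluded=excluded)


def select_specificity_mutations(target_table: EnrichmentTable,
                                 competitor_tables: list[EnrichmentTable],
                                 enrich_min: float, deplete_max: float,
                                 missing_fails: bool = True,
                                 include_stop: bool = False) -> list[tuple[int, str]]:
    """Mutations enriched on-target and depleted against every competitor.

    Returns (position, amino_acid) pairs with target e-ratio >= enrich_min
    and e-ratio <= deplete_max in every competitor table, sorted by target
    e-ratio descending. Wild-type cells are not mutations and are never
    returned. A missing competitor cell fails the test by default
    (conservative: no evidence of depletion).
    """
    if not competitor_tables:
        raise ValueError("specificity is undefined without competitor tables")
    for comp in competitor_tables:
        if comp.reference != target_table.reference:
            raise ValueError("all tables must share the reference sequence")

    columns = COLUMNS if include_stop else AMINO_ACIDS
    hits = []
    for pos in target_table.positions:
        wt = target_table.reference[pos - 1]
        for aa in columns:
            if aa == wt:
                continue
            val = target_table.eratio.loc[pos, aa]
            if pd.isna(val) or val < enrich_min:
                continue
            ok = True
            for comp in competitor_tables:
                cval = comp.eratio.loc[pos, aa]
                if pd.isna(cval):
                    if missing_fails:
                        ok = False
                        break
                elif cval > deplete_max:
                    ok = False
                    break
            if ok:
                hits.append((float(val), int(pos), aa))
    hits.sort(key=lambda h: (-h[0], h[1], h[2]))
    return [(pos, aa) for _, pos, aa in hits]


def detect_destabilizing_enrichment(table: EnrichmentTable,
                                    threshold: float) -> list[tuple[int, str]]:
    """Positions where proline or stop substitutions are enriched.

    Enrichment of prolines or premature stops signals selection for an
    unfolded state that exposes the BH3-mimetic helix, rather than for
    specific binding by the intact bundle. Returns (position, tag) with tag
    in {"proline", "stop", "both"}.
    """
    out = []
    for pos in table.positions:
        pro = table.eratio.loc[pos, "P"]
        stop = table.eratio.loc[pos, STOP]
        pro_hit = (not pd.isna(pro)) and pro >= threshold
        stop_hit = (not pd.isna(stop)) and stop >= threshold
        if pro_hit and stop_hit:
            out.append((int(pos), "both"))
        elif pro_hit:
            out.append((int(pos), "proline"))
        elif stop_hit:
            out.append((int(pos), "stop"))
    return out


# ---------------------------------------------------------------------------
# TSV interfaces


def write_enrichment_tsv(table: EnrichmentTable, path) -> None:
    table.eratio.to_csv(path, sep="\t", na_rep="NA")


def read_enrichment_tsv(path, reference: str,
                        designed_sequence: str | None = None,
                        pseudocount: float = float("nan")) -> EnrichmentTable:
    eratio = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
    eratio.index.name = "position"
    missing_frac = eratio.isna().sum(axis=1) / len(COLUMNS)
    mask = pd.Series(
        np.where(missing_frac > 0.5, MASK_INSUFFICIENT, MASK_OK), index=eratio.index
    )
    return EnrichmentTable(eratio=eratio, mask=mask, pseudocount=pseudocount,
                           reference=reference,
                           designed_sequence=designed_sequence or reference)


def write_count_table_tsv(naive: VariantCountTable, sorted_pool: VariantCountTable,
                          path) -> None:
    """Long-format TSV: position, wt_aa, mut_aa, count_naive, count_sorted."""
    if naive.reference != sorted_pool.reference:
        raise ValueError("pools must share the reference sequence")
    rows = []
    for pos in naive.counts.index:
        wt = naive.reference[pos - 1]
        for aa in COLUMNS:
            cn = naive.wildtype_count if aa == wt else int(naive.counts.loc[pos, aa])
            cs = (sorted_pool.wildtype_count if aa == wt
                  else int(sorted_pool.counts.loc[pos, aa]))
            rows.append((pos, wt, aa, cn, cs))
    pd.DataFrame(
        rows, columns=["position", "wt_aa", "mut_aa", "count_naive", "count_sorted"]
    ).to_csv(path, sep="\t", index=False)


def read_count_table_tsv(path) -> tuple[VariantCountTable, VariantCountTable]:
    df = pd.read_csv(path, sep="\t")
    length = int(df["position"].max())
    reference = ["X"] * length
    for pos, wt in zip(df["position"], df["wt_aa"]):
        reference[pos - 1] = wt
    reference = "".join(reference)
    tables = []
    for col, label in (("count_naive", "naive"), ("count_sorted", "sorted")):
        counts = _empty_counts(length)
        wt_counts = []
        for _, row in df.iterrows():
            pos, aa = int(row["position"]), row["mut_aa"]
            if aa == reference[pos - 1]:
                wt_counts.append(int(row[col]))
            else:
                counts.loc[pos, aa] = int(row[col])
        wt_set = set(wt_counts)
        if len(wt_set) > 1:
            warnings.warn("wild-type tallies differ across positions; using the first")
        tables.append(VariantCountTable(
            reference=reference, counts=counts, pool_label=label,
            wildtype_count=wt_counts[0] if wt_counts else 0,
        ))
    return tables[0], tables[1]
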