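"""Alignment-based conservation by amino-acid category and BH3 register.

Conservation across an alignment of inhibitors (or of the BCL2 homologs
themselves) is scored by counting, per column, how many distinct
physicochemical categories of amino acid appear. Sequences are also
shaded against a consensus (identical / similar / different), and the
BH3 hotspot register h0-h4 is tracked, including whole-register shifts
such as the one-helical-turn (+4) shift of the Bcl-w-targeting inhibitor.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

GAP_CHARS = set("-.")

# Physicochemical categories. The partition is configurable; this default
# groups aliphatic-nonpolar, aromatic, polar-uncharged, positive, negative
# and conformationally special residues.
DEFAULT_SCHEME = {
    "aliphatic": set("AVLIM"),
    "aromatic": set("FWY"),
    "polar": set("STNQC"),
    "positive": set("KRH"),
    "negative": set("DE"),
    "special": set("GP"),
}


def category_of(aa: str, scheme: dict | None = None) -> str:
    scheme = scheme or DEFAULT_SCHEME
    aa = aa.upper()
    for name, members in scheme.items():
        if aa in members:
            return name
    raise ValueError(f"amino acid {aa!r} not in any category of the scheme")


def _as_strings(alignment) -> list[str]:
    return [str(getattr(s, "seq", s)).upper() for s in alignment]


def conservation_category_count(alignment, scheme: dict | None = None) -> list[int]:
    """Number of distinct amino-acid categories per alignment column.

    Gaps are ignored; a column of only gaps scores 0. A lower count means
    a more conserved physicochemical environment. Raises on ragged input.
    """
    seqs = _as_strings(alignment)
    if not seqs:
        raise ValueError("empty alignment")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("ragged alignment: sequences differ in length")
    counts = []
    for col in range(length):
        cats = {category_of(s[col], scheme) for s in seqs if s[col] not in GAP_CHARS}
        counts.append(len(cats))
    return counts


IDENTICAL, SIMILAR, DIFFERENT = "identical", "similar", "different"


def consensus_shading(sequence, consensus, scheme: dict | None = None) -> list[str]:
    """Classify each residue against the consensus.

    identical if equal; similar if in the same category (the shading a
    sequence figure renders gray); different otherwise (black). Gaps in
    either sequence classify as different.
    """
    seq = str(getattr(sequence, "seq", sequence)).upper()
    cons = str(getattr(consensus, "seq", consensus)).upper()
    if len(seq) != len(cons):
        raise ValueError("sequence and consensus lengths differ")
    out = []
    for a, c in zip(seq, cons):
        if a == c:
            out.append(IDENTICAL)
        elif a in GAP_CHARS or c in GAP_CHARS:
            out.append(DIFFERENT)
        elif category_of(a, scheme) == category_of(c, scheme):
            out.append(SIMILAR)
        else:
            out.append(DIFFERENT)
    return out


# ---------------------------------------------------------------------------
# BH3 register

# Hotspots sit on five consecutive turns of the BH3 helix; successive
# hotspots alternate +4/+3 residues (one helical turn each).
HOTSPOT_OFFSETS = {"h0": 0, "h1": 4, "h2": 7, "h3": 11, "h4": 14}

_LABEL_RE = re.compile(r"^(h[0-4])([+-]\d+)?$")


@dataclass
class BH3Register:
    """Positions of BH3 hotspots h0-h4 on a given sequence.

    ``anchor`` is the 1-based sequence position of h0; labels like
    "h2+1" address offsets from a hotspot. ``register_shift`` records a
    uniform shift of the whole register (+4 = one helical turn toward the
    C terminus, as in the Bcl-w-targeting inhibitor).
    """

    anchor: int
    register_shift: int = 0
    sequence_length: int | None = None
    offsets: dict = field(default_factory=lambda: dict(HOTSPOT_OFFSETS))

    def __post_init__(self) -> None:
        if self.anchor < 1:
            raise ValueError("anchor must be a 1-based position")
        self._check_bounds()

    def _check_bounds(self) -> None:
        if self.sequence_length is None:
            return
        for label in self.offsets:
            pos = self.position(label)
            if pos < 1 or pos > self.sequence_length:
                raise ValueError(
                    f"hotspot {label} maps to position {pos}, outside 1.."
                    f"{self.sequence_length}")

    def position(self, label: str) -> int:
        """Sequence position of a hotspot label, e.g. "h3" or "h1+2"."""
        m = _LABEL_RE.match(label)
        if not m:
            raise ValueError(f"bad hotspot label {label!r}")
        hotspot, extra = m.group(1), int(m.group(2) or 0)
        return self.anchor + self.offsets[hotspot] + extra + self.register_shift

    def hotspot_positions(self) -> dict:
        return {label: self.position(label) for label in sorted(self.offsets)}


def apply_register_shift(register: BH3Register, shift: int) -> BH3Register:
    """Shift every hotspot position uniformly by ``shift`` residues.

    Raises if any shifted hotspot would fall outside the sequence bounds
    (when the register knows its sequence length).
    """
    return BH3Register(anchor=register.anchor,
                       register_shift=register.register_shift + shift,
                       sequence_length=register.sequence_length,
                       offsets=dict(register.offsets))


def map_structure_conservation(scores, model, chain: str,
                               column_to_residue: dict | None = None) -> pd.DataFrame:
    """Attach per-column conservation scores to residues of a chain.

    ``column_to_residue`` maps 1-based alignment columns to residue
    numbers; by default columns map to the chain's residues in order.
    Returns a table (residue_number, score, mapped); residues without a
    column, and columns without a residue, are flagged rather than fatal.
    """
    residues = model.residues(chain)
    if not residues:
        raise ValueError(f"chain {chain!r} has no residues")
    if column_to_residue is None:
        column_to_residue = {i + 1: res.number for i, res in enumerate(residues)}
    resnums = {res.number for res in residues}
    rows = []
    for col, score in enumerate(scores, start=1):
        resnum = column_to_residue.get(col)
        mapped = resnum is not None and resnum in resnums
        rows.append({"column": col, "residue_number": resnum,
                     "score": score, "mapped": mapped})
    return pd.DataFrame(rows).set_index("column")
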