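"""Molecular properties and lipidation-site heuristics.

Molecular weight follows the ProtParam convention (sum of average residue
masses plus one water); the isoelectric point solves net charge = 0 by
bisection over Henderson-Hasselbalch terms with a Bjellqvist-style pKa table
(an EMBOSS table is selectable).  Myristoylation and palmitoylation are
predicted with transparent consensus rules — a PROSITE-style N-myristoylation
pattern at Gly-2 and an N-terminal cysteine window — and are labelled as
heuristic in all outputs; proteins carrying either kind of site are called
membrane-targeted, all others cytoplasm/nucleus.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core_io import ConfigError, ValidationError

__all__ = [
    "PropertyRecord",
    "AVERAGE_RESIDUE_MASS",
    "PKA_TABLES",
    "molecular_weight",
    "isoelectric_point",
    "net_charge",
    "predict_myristoylation",
    "predict_palmitoylation",
    "predict_localization",
    "compute_properties",
]

#: Average residue (amino acid minus water) masses in daltons.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
    "X": 110.0,  # ambiguity code: average residue mass
}

WATER_MASS = 18.015

#: pKa tables for the ionizable groups.  'bjellqvist' is the default
#: (ProtParam-style); 'emboss' is the EMBOSS iep table.
PKA_TABLES = {
    "bjellqvist": {
        "n_term": 7.5, "c_term": 3.55,
        "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,
        "H": 5.98, "K": 10.0, "R": 12.0,
    },
    "emboss": {
        "n_term": 8.6, "c_term": 3.6,
        "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
        "H": 6.5, "K": 10.8, "R": 12.5,
    },
}

_NEGATIVE = ("D", "E", "C", "Y")
_POSITIVE = ("H", "K", "R")


@dataclass
class PropertyRecord:
    """Computed molecular properties and heuristic lipidation calls."""

    protein_id: str
    length: int
    mw_kda: float
    pi: float
    myristoylation: bool
    myristoylation_site: int | None   # always residue 2 (the Gly) when set
    palmitoylation: list[int]         # 1-based Cys positions
    localization: str                 # 'membrane' | 'cytoplasm_nucleus'

    def __post_init__(self) -> None:
        if not 0 < self.pi < 14:
            raise ValidationError(f"{self.protein_id}: pI out of range")
        if self.mw_kda <= 0:
            raise ValidationError(f"{self.protein_id}: non-positive MW")
        if self.myristoylation_site is not None and self.myristoylation_site != 2:
            raise ValidationError(
                f"{self.protein_id}: myristoylation site must be residue 2"
            )


def molecular_weight(seq: str) -> float:
    """Average molecular weight in kDa (one decimal is the display precision)."""
    if not seq:
        raise ValidationError("empty sequence")
    try:
        total = sum(AVERAGE_RESIDUE_MASS[a] for a in seq) + WATER_MASS
    except KeyError as exc:
        raise ValidationError(f"unknown residue {exc.args[0]!r}")
    return total / 1000.0


def net_charge(seq: str, ph: float, table: str = "bjellqvist") -> float:
    """Net charge Q(pH) from Henderson-Hasselbalch terms.

    Positive groups (N-terminus, H, K, R) contribute 1/(1+10^(pH-pKa)),
    negative groups (C-terminus, D, E, C, Y) contribute -1/(1+10^(pKa-pH)).
    """
    pka = PKA_TABLES[table]
    counts = {aa: seq.count(aa) for aa in _NEGATIVE + _POSITIVE}
    q = 1.0 / (1.0 + 10 ** (ph - pka["n_term"]))
    q -= 1.0 / (1.0 + 10 ** (pka["c_term"] - ph))
    for aa in _POSITIVE:
        q += counts[aa] / (1.0 + 10 ** (ph - pka[aa]))
    for aa in _NEGATIVE:
        q -= counts[aa] / (1.0 + 10 ** (pka[aa] - ph))
    return q


def isoelectric_point(seq: str, table: str = "bjellqvist") -> float:
    """The pH at which the net charge vanishes, found by bisection.

    Converges when |Q| < 1e-4; a tiny interval-width guard (1e-10 pH) stops
    the search once floating point stops making progress.  The charge curve
    is strictly decreasing in pH, so the root is unique.
    """
    if not seq:
        raise ValidationError("empty sequence")
    if table not in PKA_TABLES:
        raise ConfigError(f"unknown pKa table {table!r}")
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = net_charge(seq, mid, table)
        if abs(q) < 1e-4 or hi - lo < 1e-10:
            return mid
        if q > 0:     # still positively charged: pI is higher
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


#: N-myristoylation consensus applied to mature positions 1..6 after
#: initiator-Met removal: G-{EDRKHPFYW}-x(2)-[STAGCN]-{P}.
_MYR_FORBIDDEN_2 = set("EDRKHPFYW")
_MYR_ALLOWED_5 = set("STAGCN")


def predict_myristoylation(seq: str) -> tuple[bool, int | None]:
    """True iff the protein starts Met-Gly and the mature N-terminus
    matches the consensus; the modified residue is always Gly-2."""
    if len(seq) < 7 or seq[0] != "M" or seq[1] != "G":
        return False, None
    mature = seq[1:]
    if mature[1] in _MYR_FORBIDDEN_2:
        return False, None
    if mature[4] not in _MYR_ALLOWED_5:
        return False, None
    if mature[5] == "P":
        return False, None
    return True, 2


def predict_palmitoylation(seq: str, window: int = 25) -> list[int]:
    """1-based positions of cysteines within the first ``window`` residues."""
    if window < 1:
        raise ConfigError("palmitoylation window must be >= 1")
    return [i + 1 for i, aa in enumerate(seq[:window]) if aa == "C"]


def predict_localization(myr: bool, palm: list[int]) -> str:
    """Membrane iff any lipidation site; else cytoplasm/nucleus."""
    return "membrane" if (myr or palm) else "cytoplasm_nucleus"


def compute_properties(
    protein_id: str, seq: str, palm_window: int = 25, pka_table: str = "bjellqvist"
) -> PropertyRecord:
    myr, site = predict_myristoylation(seq)
    palm = predict_palmitoylation(seq, window=palm_window)
    return PropertyRecord(
        protein_id=protein_id,
        length=len(seq),
        mw_kda=molecular_weight(seq),
        pi=isoelectric_point(seq, table=pka_table),
        myristoylation=myr,
        myristoylation_site=site,
        palmitoylation=palm,
        localization=predict_localization(myr, palm),
    )
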