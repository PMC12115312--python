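"""Kinase-domain and EF-hand motif detection, and architecture typing.

The calmodulin-like domain of a calcium-dependent protein kinase (CPK)
carries up to four EF-hand motifs; each motif's 12-residue loop either
matches the canonical calcium-binding loop pattern (PROSITE PS00018, a
functional Ca2+-binding site) or is degenerate.  The kinase domain is
recognised through three ordered anchor motifs: the Walker-lysine context
([AV]-x-[IV]-K of the VAIK motif), the catalytic HRD, and the activation-loop
DFG.  Architectures built from these hits are clustered per ortholog group
into a representative (majority) type and minority variants, with singleton
layouts set aside.

Generalized PROSITE *profiles* (PS50011/PS50222) are not reimplemented here;
the anchor-motif and loop-pattern scanners are the built-in path, and
:func:`load_external_domains` accepts precomputed ScanProsite/InterProScan
style tables for real proteomes.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .core_io import ConfigError, ProteinRecord, ValidationError, read_table

__all__ = [
    "PrositePattern",
    "PS00018",
    "CA_LOOP_LENGTH",
    "COORDINATING_POSITIONS",
    "DomainHit",
    "Architecture",
    "ArchitectureClassification",
    "match_pattern",
    "scan_ef_hands",
    "scan_kinase",
    "scan_protein",
    "load_external_domains",
    "build_architecture",
    "classify_family",
    "cluster_architectures",
    "FAMILY_ARCH_RULES",
]


# ---------------------------------------------------------------------------
# PROSITE pattern machinery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Element:
    """One pattern position: allowed/forbidden residue class or wildcard run."""

    kind: str           # 'literal' | 'allowed' | 'forbidden' | 'wildcard'
    residues: frozenset[str] = frozenset()
    min_n: int = 1
    max_n: int = 1

    def accepts(self, residue: str) -> bool:
        if self.kind == "wildcard":
            return True
        if residue == "X":
            # The ambiguity code never satisfies a constrained position.
            return False
        if self.kind == "forbidden":
            return residue not in self.residues
        return residue in self.residues


_TOKEN_RE = re.compile(
    r"(?P<lit>[A-Z])|\[(?P<allow>[A-Z]+)\]|\{(?P<forbid>[A-Z]+)\}|x|"
    r"\((?P<rep>\d+(?:,\d+)?)\)"
)


@dataclass(frozen=True)
class PrositePattern:
    """A parsed PROSITE-syntax pattern, e.g. ``D-x-[DNS]-{ILVFYW}-...``."""

    id: str
    elements: tuple[_Element, ...]

    @classmethod
    def parse(cls, text: str, id: str = "") -> "PrositePattern":
        elements: list[_Element] = []
        for token in text.strip().rstrip(".").split("-"):
            token = token.strip()
            if not token:
                raise ConfigError(f"pattern {id!r}: empty element")
            pos = 0
            base: _Element | None = None
            while pos < len(token):
                m = _TOKEN_RE.match(token, pos)
                if m is None:
                    raise ConfigError(
                        f"pattern {id!r}: cannot parse element {token!r}"
                    )
                if m.group("rep") is not None:
                    if base is None or base.kind != "wildcard":
                        raise ConfigError(
                            f"pattern {id!r}: repeat without wildcard in {token!r}"
                        )
                    parts = m.group("rep").split(",")
                    lo = int(parts[0])
                    hi = int(parts[-1])
                    if lo < 1 or lo > hi:
                        raise ConfigError(
                            f"pattern {id!r}: bad repeat range in {token!r}"
                        )
                    base = _Element("wildcard", min_n=lo, max_n=hi)
                elif m.group("lit"):
                    base = _Element("literal", frozenset(m.group("lit")))
                elif m.group("allow"):
                    base = _Element("allowed", frozenset(m.group("allow")))
                elif m.group("forbid"):
                    base = _Element("forbidden", frozenset(m.group("forbid")))
                else:
                    base = _Element("wildcard")
                pos = m.end()
            elements.append(base)
        if not elements:
            raise ConfigError(f"pattern {id!r}: no elements")
        return cls(id=id, elements=tuple(elements))

    @property
    def fixed_length(self) -> int | None:
        """Window length when every element has a fixed width, else None."""
        total = 0
        for el in self.elements:
            if el.min_n != el.max_n:
                return None
            total += el.min_n
        return total


#: Canonical EF-hand calcium-binding loop pattern (13 positions).
PS00018 = PrositePattern.parse(
    "D-x-[DNS]-{ILVFYW}-[DENSTG]-[DNQGHRK]-{GP}-[LIVMC]-[DENQSTAGC]-x(2)-[DE]-[LIVMFYW]",
    id="PS00018",
)

#: Window length of the calcium-binding loop pattern.
CA_LOOP_LENGTH = 13

#: Loop positions whose side chains coordinate the calcium ion (1-based
#: within the 13-position window; the canonical X, Y, Z, -X, -Z positions).
COORDINATING_POSITIONS = (1, 3, 5, 9, 12)


def match_pattern(sequence: str, pattern: PrositePattern) -> list[tuple[int, int]]:
    """All matches of ``pattern`` in ``sequence`` as 0-based half-open spans.

    Every start position is tried and overlapping matches are all reported,
    sorted by start.  Variable-width wildcards are matched greedily shortest
    first; for each start only the first realised span is reported.
    """
    matches: list[tuple[int, int]] = []
    n = len(sequence)

    def extend(idx: int, el_idx: int) -> int | None:
        if el_idx == len(pattern.elements):
            return idx
        el = pattern.elements[el_idx]
        if el.kind == "wildcard":
            for width in range(el.min_n, el.max_n + 1):
                if idx + width > n:
                    break
                end = extend(idx + width, el_idx + 1)
                if end is not None:
                    return end
            return None
        if idx >= n or not el.accepts(sequence[idx]):
            return None
        return extend(idx + 1, el_idx + 1)

    for start in range(n):
        end = extend(start, 0)
        if end is not None:
            matches.append((start, end))
    return matches


def _expand_fixed(pattern: PrositePattern) -> list[_Element]:
    """One element per window position (fixed-width patterns only)."""
    out: list[_Element] = []
    for el in pattern.elements:
        if el.min_n != el.max_n:
            raise ConfigError(f"pattern {pattern.id!r} is not fixed-width")
        out.extend([el] * el.min_n)
    return out


#: Per-position residue classes of the 13-residue calcium-binding loop.
_LOOP_POSITIONS = _expand_fixed(PS00018)


def _loop_violations(window: str) -> tuple[int, bool, bool] | None:
    """Check a 13-residue window against the calcium-loop position classes.

    Returns (violations among coordinating positions, pos-1 anchor ok,
    pos-12 anchor ok) when all non-coordinating positions match, else None.
    """
    if len(window) != CA_LOOP_LENGTH:
        return None
    coord = set(COORDINATING_POSITIONS)
    violations = 0
    anchor1 = anchor12 = True
    for i, el in enumerate(_LOOP_POSITIONS, start=1):
        ok = el.accepts(window[i - 1])
        if i in coord:
            if not ok:
                violations += 1
                if i == 1:
                    anchor1 = False
                elif i == 12:
                    anchor12 = False
        elif not ok:
            return None
    return violations, anchor1, anchor12


# ---------------------------------------------------------------------------
# Domain hits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainHit:
    """A kinase-domain or EF-hand span on a protein (0-based half-open)."""

    kind: str                 # 'KINASE' | 'EF_HAND'
    start: int
    end: int
    complete: bool | None = None   # KINASE only
    ca_site: bool | None = None    # EF_HAND only
    evidence: str = "builtin_scan"

    def __post_init__(self) -> None:
        if self.kind not in ("KINASE", "EF_HAND"):
            raise ValidationError(f"unknown domain kind {self.kind!r}")
        if not self.start < self.end:
            raise ValidationError("domain hit start must be < end")


def scan_ef_hands(protein: ProteinRecord) -> list[DomainHit]:
    """Detect EF-hand loops: strict calcium-loop matches are functional
    (ca_site=True); loops with 1-2 violated coordinating positions but at
    least one intact anchor (D at position 1 or D/E at position 12) are
    degenerate (ca_site=False).

    Overlapping candidate windows are resolved greedily left to right,
    keeping non-overlapping hits; a strict match wins over a relaxed one at
    the same start.
    """
    seq = protein.sequence
    candidates: list[tuple[int, bool]] = []  # (start, ca_site)
    for start in range(len(seq) - CA_LOOP_LENGTH + 1):
        res = _loop_violations(seq[start : start + CA_LOOP_LENGTH])
        if res is None:
            continue
        violations, anchor1, anchor12 = res
        if violations == 0:
            candidates.append((start, True))
        elif violations <= 2 and (anchor1 or anchor12):
            candidates.append((start, False))

    hits: list[DomainHit] = []
    last_end = -1
    for start, ca in candidates:  # already sorted by start; strict first at ties
        if start < last_end:
            continue
        hits.append(
            DomainHit("EF_HAND", start, start + CA_LOOP_LENGTH, ca_site=ca)
        )
        last_end = start + CA_LOOP_LENGTH
    return hits


#: Kinase anchor motifs, in their within-domain order.
KINASE_ANCHORS = (
    ("VAIK", re.compile(r"[AV].[IV]K")),
    ("HRD", re.compile(r"HRD")),
    ("DFG", re.compile(r"DFG")),
)

#: Allowed first-to-last anchor span of a complete kinase domain (residues).
KINASE_SPAN_RANGE = (180, 340)
KINASE_PAD = 25


def scan_kinase(protein: ProteinRecord) -> DomainHit | None:
    """Detect the kinase domain through its three ordered anchor motifs.

    complete=True iff Walker-lysine, HRD and DFG all occur in order with a
    first-to-last span inside :data:`KINASE_SPAN_RANGE`; 1-2 anchors present
    gives an incomplete hit; none gives no hit.  The reported span pads the
    anchor extent by 25 residues, clipped to the protein.
    """
    seq = protein.sequence
    occs = [
        [(m.start(), m.end()) for m in rx.finditer(seq)]
        for _, rx in KINASE_ANCHORS
    ]
    lo, hi = KINASE_SPAN_RANGE

    best: tuple[int, int] | None = None
    for ws, we in occs[0]:
        for hs, he in occs[1]:
            if hs < we:
                continue
            for ds, de in occs[2]:
                if ds < he:
                    continue
                span = de - ws
                if lo <= span <= hi:
                    best = (ws, de)
                    break
            if best:
                break
        if best:
            break

    if best is not None:
        start = max(0, best[0] - KINASE_PAD)
        end = min(len(seq), best[1] + KINASE_PAD)
        return DomainHit("KINASE", start, end, complete=True)

    present = [o[0] for o in occs if o]
    if not present:
        return None
    first = min(s for s, _ in present)
    last = max(e for _, e in present)
    start = max(0, first - KINASE_PAD)
    end = min(len(seq), last + KINASE_PAD)
    return DomainHit("KINASE", start, end, complete=False)


def scan_protein(protein: ProteinRecord) -> list[DomainHit]:
    """Full built-in scan: kinase hit (if any) followed by EF-hand hits.

    EF-hand windows overlapping the kinase span are suppressed so the two
    scanners partition the sequence.
    """
    hits: list[DomainHit] = []
    kin = scan_kinase(protein)
    if kin is not None:
        hits.append(kin)
    for ef in scan_ef_hands(protein):
        if kin is not None and ef.start < kin.end and kin.start < ef.end:
            continue
        hits.append(ef)
    return hits


def load_external_domains(path: str | Path) -> dict[str, list[DomainHit]]:
    """Read a precomputed domain table (ScanProsite/InterProScan style).

    Expected columns: protein_id, source_id in {PS50011, PS50222, PS00018},
    start, end (1-based inclusive).  PS50011 rows become complete kinase
    hits, PS50222 rows EF-hands; an EF-hand is flagged as a functional
    Ca2+-binding site iff a PS00018 row lies within its span.  Orphan PS00018
    rows are attached to the nearest EF-hand within 5 residues or dropped
    with a warning.
    """
    df = read_table(
        path,
        required={"protein_id": str, "source_id": str, "start": int, "end": int},
    )
    known = {"PS50011", "PS50222", "PS00018"}
    bad = set(df["source_id"]) - known
    if bad:
        raise ValidationError(f"unknown source_id value(s): {sorted(bad)}")

    out: dict[str, list[DomainHit]] = {}
    for pid, rows in df.groupby("protein_id", sort=False):
        efs: list[tuple[int, int, bool]] = []  # start, end, ca_site
        kinases: list[tuple[int, int]] = []
        ca_rows: list[tuple[int, int]] = []
        for _, r in rows.iterrows():
            s, e = int(r["start"]) - 1, int(r["end"])
            if r["source_id"] == "PS50011":
                kinases.append((s, e))
            elif r["source_id"] == "PS50222":
                efs.append((s, e, False))
            else:
                ca_rows.append((s, e))
        for cs, ce in ca_rows:
            placed = False
            for i, (s, e, _) in enumerate(efs):
                if s <= cs and ce <= e:
                    efs[i] = (s, e, True)
                    placed = True
                    break
            if not placed:
                # Attach to the nearest EF-hand within 5 residues, else drop.
                dists = [
                    (max(s - ce, cs - e, 0), i) for i, (s, e, _) in enumerate(efs)
                ]
                dists = [d for d in dists if d[0] <= 5]
                if dists:
                    _, i = min(dists)
                    s, e, _ = efs[i]
                    efs[i] = (s, e, True)
                    warnings.warn(
                        f"{pid}: Ca-site row at {cs + 1}..{ce} outside EF spans; "
                        "attached to nearest EF-hand"
                    )
                else:
                    warnings.warn(
                        f"{pid}: Ca-site row at {cs + 1}..{ce} not inside or near "
                        "any EF-hand span; dropped"
                    )
        hits = [
            DomainHit("KINASE", s, e, complete=True, evidence="external_table")
            for s, e in kinases
        ] + [
            DomainHit("EF_HAND", s, e, ca_site=ca, evidence="external_table")
            for s, e, ca in sorted(efs)
        ]
        out[pid] = hits
    return out


# ---------------------------------------------------------------------------
# Architectures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Architecture:
    """Domain layout of one protein: kinase state plus ordered EF-hands.

    ``signature`` is a pure function of the other fields, e.g. a canonical
    CPK is ``K|E*E*E*E*`` (complete kinase, four EF-hands, all with
    Ca2+-binding sites); an incomplete kinase is lowercase ``k``.
    """

    kinase_state: str                  # 'complete' | 'incomplete' | 'absent'
    ef_hands: tuple[bool, ...] = ()    # per EF-hand: functional Ca-site?
    lobes: tuple[str, ...] = ()        # per EF-hand: 'N' | 'C' | 'none'

    def __post_init__(self) -> None:
        if self.kinase_state not in ("complete", "incomplete", "absent"):
            raise ValidationError(f"bad kinase_state {self.kinase_state!r}")
        if len(self.lobes) != len(self.ef_hands):
            raise ValidationError("lobes and ef_hands must have equal length")

    @property
    def ef_count(self) -> int:
        return len(self.ef_hands)

    @property
    def ca_count(self) -> int:
        return sum(self.ef_hands)

    @property
    def signature(self) -> str:
        if self.kinase_state == "absent" and not self.ef_hands:
            return ""
        kpart = {"complete": "K", "incomplete": "k", "absent": ""}[self.kinase_state]
        efpart = "".join("E*" if ca else "E" for ca in self.ef_hands)
        return f"{kpart}|{efpart}"


def build_architecture(hits: list[DomainHit], protein_length: int) -> Architecture:
    """Assemble an architecture from non-overlapping domain hits.

    EF-hands are ordered N- to C-terminal.  When the protein has a kinase
    domain and at least two EF-hands, the last two EF-hands form the C-lobe
    of the calmodulin-like domain and all preceding ones the N-lobe;
    otherwise no lobe is assigned.
    """
    kinases = [h for h in hits if h.kind == "KINASE"]
    if len(kinases) > 1:
        raise ValidationError("more than one kinase domain hit")
    for h in hits:
        if h.end > protein_length:
            raise ValidationError("domain hit extends past protein end")
    efs = sorted((h for h in hits if h.kind == "EF_HAND"), key=lambda h: h.start)
    for a, b in zip(efs, efs[1:]):
        if b.start < a.end:
            raise ValidationError("overlapping EF-hand hits")

    if kinases:
        kinase_state = "complete" if kinases[0].complete else "incomplete"
    else:
        kinase_state = "absent"
    flags = tuple(bool(h.ca_site) for h in efs)
    if kinases and len(flags) >= 2:
        lobes = tuple(
            "C" if i >= len(flags) - 2 else "N" for i in range(len(flags))
        )
    else:
        lobes = ("none",) * len(flags)
    return Architecture(kinase_state=kinase_state, ef_hands=flags, lobes=lobes)


# ---------------------------------------------------------------------------
# Family classification
# ---------------------------------------------------------------------------

#: Expected layout per family, used for the domain-consistency check.
FAMILY_ARCH_RULES = {
    "CCaMK": dict(kinase="complete", ef_min=3, ef_max=3),
    "CPK": dict(kinase="complete", ef_min=3, ef_max=4),
    "CRK": dict(kinase=None, ef_min=0, ef_max=1, no_ca=True),
    "PEPRK": dict(kinase=None, ef_min=0, ef_max=0),
    "PPCK": dict(kinase=None, ef_min=0, ef_max=0),
}

#: Default raw local-alignment score floor below which no family is assigned.
DEFAULT_SCORE_FLOOR = 100.0


def _make_aligner():
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    matrix = substitution_matrices.load("BLOSUM62")
    # The ambiguity code X contributes nothing to similarity.
    arr = matrix.copy()
    if "X" in arr.alphabet:
        xi = arr.alphabet.index("X")
        arr[xi, :] = 0.0
        arr[:, xi] = 0.0
    aligner.substitution_matrix = arr
    aligner.mode = "local"
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = None


def alignment_score(seq_a: str, seq_b: str) -> float:
    """Local alignment score (BLOSUM62, gap open 11 / extend 1)."""
    global _ALIGNER
    if _ALIGNER is None:
        _ALIGNER = _make_aligner()
    return float(_ALIGNER.score(seq_a, seq_b))


def classify_family(
    protein: ProteinRecord,
    seeds: dict[str, list[ProteinRecord]],
    arch: Architecture | None = None,
    score_floor: float = DEFAULT_SCORE_FLOOR,
) -> tuple[str, float, list[str]]:
    """Assign a kinase family by best local-alignment score against seeds.

    ``seeds`` maps family label -> labelled seed proteins.  The best-scoring
    seed's family is returned with its score; a score below ``score_floor``
    yields label 'none'.  When an architecture is supplied, a warning is
    appended for each way the label's expected domain layout is violated.
    """
    if not seeds or not any(seeds.values()):
        raise ConfigError("empty seed set")
    best_family, best_score = "none", float("-inf")
    for family, members in seeds.items():
        for seed in members:
            score = alignment_score(protein.sequence, seed.sequence)
            if score > best_score:
                best_family, best_score = family, score
    if best_score < score_floor:
        return "none", best_score, []

    warnings_out: list[str] = []
    if arch is not None and best_family in FAMILY_ARCH_RULES:
        rules = FAMILY_ARCH_RULES[best_family]
        if rules["kinase"] == "complete" and arch.kinase_state != "complete":
            warnings_out.append(
                f"{best_family} expects a complete kinase domain, "
                f"found {arch.kinase_state}"
            )
        elif arch.kinase_state == "absent":
            warnings_out.append(f"{best_family} expects a kinase domain, found none")
        if not rules["ef_min"] <= arch.ef_count <= rules["ef_max"]:
            warnings_out.append(
                f"{best_family} expects {rules['ef_min']}-{rules['ef_max']} "
                f"EF-hands, found {arch.ef_count}"
            )
        if rules.get("no_ca") and arch.ca_count > 0:
            warnings_out.append(
                f"{best_family} EF-hands should lack Ca2+-binding sites, "
                f"found {arch.ca_count}"
            )
    return best_family, best_score, warnings_out


# ---------------------------------------------------------------------------
# Architecture clustering (representative vs variants)
# ---------------------------------------------------------------------------

@dataclass
class ArchitectureClassification:
    """Representative/variant split of the architectures in one gene group."""

    group: str
    representative: Architecture | None
    representative_support: int
    variants: list[tuple[Architecture, int]] = field(default_factory=list)
    solo_excluded: list[Architecture] = field(default_factory=list)
    all_solo: bool = False


def cluster_architectures(
    members: list[tuple[str, Architecture]], group: str = ""
) -> ArchitectureClassification:
    """Split a group's architectures into the representative type (majority
    layout), minority variants, and excluded singleton ('solo') layouts.

    Architectures are compared by signature.  Support ties are broken by
    more total Ca2+-binding sites, then by lexicographically smaller
    signature.  If every layout is solo, the classification is flagged and
    has no representative.
    """
    by_sig: dict[str, tuple[Architecture, int]] = {}
    for _, arch in members:
        sig = arch.signature
        if sig in by_sig:
            a, n = by_sig[sig]
            by_sig[sig] = (a, n + 1)
        else:
            by_sig[sig] = (arch, 1)

    solo = [a for a, n in by_sig.values() if n == 1]
    kept = [(a, n) for a, n in by_sig.values() if n > 1]
    if not kept:
        return ArchitectureClassification(
            group=group,
            representative=None,
            representative_support=0,
            solo_excluded=sorted(solo, key=lambda a: a.signature),
            all_solo=True,
        )
    kept.sort(key=lambda an: (-an[1], -an[0].ca_count, an[0].signature))
    rep, rep_n = kept[0]
    return ArchitectureClassification(
        group=group,
        representative=rep,
        representative_support=rep_n,
        variants=kept[1:],
        solo_excluded=sorted(solo, key=lambda a: a.signature),
    )
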