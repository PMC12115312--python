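"""Collinear-block detection and duplicate-pair mode classification.

Collinear blocks are chains of homologous gene pairs in conserved order
between two chromosomes, found by longest-chain dynamic programming over
gene-order ranks (both orientations), with MCScanX-style defaults
(min_anchors 5, max_gap 25).  Duplicate gene pairs are then classified
hierarchically — WGD > tandem > proximal > transposed > dispersed — in the
style of the DupGen-finder scheme: a pair anchored in a block is
whole-genome-derived; adjacent ranks are tandem; within a proximal window,
proximal; a pair with exactly one member at an ancestral locus (an anchor in
any block against the outgroup genome) is transposed; everything left is
dispersed.  Each gene receives the mode of its highest-priority pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .core_io import ConfigError, ProteinRecord, ValidationError

__all__ = [
    "HomologPair",
    "CollinearBlock",
    "DuplicationCall",
    "MODES",
    "compute_similarity_pairs",
    "find_collinear_blocks",
    "classify_duplications",
    "build_cnv_matrix",
    "write_blocks",
    "read_homolog_pairs",
]

MODES = ("WGD", "TD", "PD", "TRD", "DSD", "SINGLETON")


@dataclass(frozen=True)
class HomologPair:
    """An unordered homologous gene pair (stored with gene_a < gene_b)."""

    gene_a: str
    gene_b: str
    score: float = 1.0

    def __post_init__(self) -> None:
        if not self.gene_a < self.gene_b:
            raise ValidationError(
                f"pair must be ordered gene_a < gene_b: {self.gene_a}, {self.gene_b}"
            )
        if self.score <= 0:
            raise ValidationError("pair score must be positive")

    @staticmethod
    def make(g1: str, g2: str, score: float = 1.0) -> "HomologPair":
        a, b = sorted((g1, g2))
        return HomologPair(a, b, score)


@dataclass
class CollinearBlock:
    """A chain of anchor pairs in conserved (or inverted) order."""

    chrom_a: str
    chrom_b: str
    anchors: list[HomologPair]
    orientation: str  # 'same' | 'inverted'
    block_id: int = -1

    @property
    def anchor_set(self) -> set[tuple[str, str]]:
        return {(p.gene_a, p.gene_b) for p in self.anchors}


@dataclass
class DuplicationCall:
    gene_id: str
    mode: str
    partner: str = ""
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValidationError(f"unknown duplication mode {self.mode!r}")
        if (self.mode == "SINGLETON") != (self.partner == ""):
            raise ValidationError("SINGLETON iff no partner")


# ---------------------------------------------------------------------------
# Similarity pairs
# ---------------------------------------------------------------------------

def compute_similarity_pairs(
    proteins: list[ProteinRecord], floor: float = 100.0
) -> list[HomologPair]:
    """All-versus-all local alignment (BLOSUM62, gap 11/1); pairs scoring at
    least ``floor`` are kept, sorted by score descending.

    A raw-score floor stands in for the E-value cutoff a BLAST-based
    pipeline would use; real tabular BLAST output can be substituted via
    :func:`read_homolog_pairs`.
    """
    from .domain_architecture import alignment_score

    if floor <= 0:
        raise ConfigError("similarity floor must be positive")
    pairs: list[HomologPair] = []
    for p1, p2 in combinations(proteins, 2):
        score = alignment_score(p1.sequence, p2.sequence)
        if score >= floor:
            pairs.append(HomologPair.make(p1.protein_id, p2.protein_id, score))
    pairs.sort(key=lambda p: (-p.score, p.gene_a, p.gene_b))
    return pairs


def read_homolog_pairs(path: str) -> list[HomologPair]:
    """Read a homology-pair TSV; accepts either a headered (gene_a, gene_b[,
    score]) table or 12-column tabular BLAST output (outfmt 6, no header)."""
    with open(path) as fh:
        first = fh.readline()
    cols = first.rstrip("\n").split("\t")
    if "gene_a" in cols and "gene_b" in cols:
        df = pd.read_csv(path, sep="\t")
        score_col = "score" if "score" in df.columns else None
        return [
            HomologPair.make(
                str(r["gene_a"]), str(r["gene_b"]),
                float(r[score_col]) if score_col else 1.0,
            )
            for _, r in df.iterrows()
            if str(r["gene_a"]) != str(r["gene_b"])
        ]
    if len(cols) == 12:
        df = pd.read_csv(path, sep="\t", header=None)
        out = {}
        for _, r in df.iterrows():
            if str(r[0]) == str(r[1]):
                continue
            p = HomologPair.make(str(r[0]), str(r[1]), float(r[11]))
            key = (p.gene_a, p.gene_b)
            if key not in out or out[key].score < p.score:
                out[key] = p
        return sorted(out.values(), key=lambda p: (-p.score, p.gene_a))
    raise ValidationError(f"unrecognized homolog-pair table format in {path}")


# ---------------------------------------------------------------------------
# Collinear block chaining
# ---------------------------------------------------------------------------

def _chain_dp(
    points: list[tuple[int, int, int]], orientation: str, max_gap: int
) -> list[int]:
    """Longest chain over (rank_a, rank_b, idx) points, strictly monotone on
    both ranks (increasing/increasing for 'same', increasing/decreasing for
    'inverted'), consecutive gaps at most ``max_gap`` on both sides.
    Returns indices of the best chain's points."""
    pts = sorted(points, key=lambda t: (t[0], t[1]))
    n = len(pts)
    best_len = [1] * n
    prev = [-1] * n
    for j in range(n):
        ra_j, rb_j, _ = pts[j]
        for i in range(j):
            ra_i, rb_i, _ = pts[i]
            if not 0 < ra_j - ra_i <= max_gap:
                continue
            if orientation == "same":
                ok = 0 < rb_j - rb_i <= max_gap
            else:
                ok = 0 < rb_i - rb_j <= max_gap
            if ok and best_len[i] + 1 > best_len[j]:
                best_len[j] = best_len[i] + 1
                prev[j] = i
    if not n:
        return []
    end = max(range(n), key=lambda j: (best_len[j], -pts[j][0]))
    chain = []
    while end != -1:
        chain.append(pts[end][2])
        end = prev[end]
    chain.reverse()
    return chain


def find_collinear_blocks(
    pairs: list[HomologPair],
    ranks: dict[str, tuple[str, int]],
    min_anchors: int = 5,
    max_gap: int = 25,
) -> list[CollinearBlock]:
    """Chain homolog pairs into collinear blocks per chromosome pair.

    ``ranks`` maps gene_id -> (chromosome, order_rank); chromosome names must
    be unique across genomes.  Chains are extracted greedily: the best chain
    over the remaining pairs wins, its pairs are removed, and chaining
    repeats until no chain reaches ``min_anchors``.  Both orientations are
    tried; each pair belongs to at most one block.
    """
    by_chrom_pair: dict[tuple[str, str], list[tuple[int, int, HomologPair]]] = {}
    for p in pairs:
        if p.gene_a not in ranks or p.gene_b not in ranks:
            raise ValidationError(f"gene missing rank: {p.gene_a} or {p.gene_b}")
        ca, ra = ranks[p.gene_a]
        cb, rb = ranks[p.gene_b]
        if ca <= cb:
            by_chrom_pair.setdefault((ca, cb), []).append((ra, rb, p))
        else:
            by_chrom_pair.setdefault((cb, ca), []).append((rb, ra, p))

    blocks: list[CollinearBlock] = []
    for (ca, cb), pts in sorted(by_chrom_pair.items()):
        remaining = list(pts)
        while True:
            indexed = [(ra, rb, i) for i, (ra, rb, _) in enumerate(remaining)]
            best_chain: list[int] = []
            best_orient = "same"
            for orient in ("same", "inverted"):
                chain = _chain_dp(indexed, orient, max_gap)
                if len(chain) > len(best_chain):
                    best_chain, best_orient = chain, orient
            if len(best_chain) < min_anchors:
                break
            anchors = [remaining[i][2] for i in best_chain]
            blocks.append(
                CollinearBlock(
                    chrom_a=ca, chrom_b=cb, anchors=anchors,
                    orientation=best_orient,
                )
            )
            chosen = set(best_chain)
            remaining = [pt for i, pt in enumerate(remaining) if i not in chosen]
    for i, b in enumerate(blocks):
        b.block_id = i
    return blocks


def write_blocks(blocks: list[CollinearBlock], path: str) -> None:
    """Write blocks in an MCScanX-like collinearity text format."""
    with open(path, "w") as fh:
        fh.write("############### panscan collinearity ###############\n")
        for b in blocks:
            fh.write(
                f"## Alignment {b.block_id}: N={len(b.anchors)} "
                f"{b.chrom_a}&{b.chrom_b} {b.orientation}\n"
            )
            for i, p in enumerate(b.anchors):
                fh.write(f"{b.block_id}-{i}:\t{p.gene_a}\t{p.gene_b}\t{p.score:g}\n")


# ---------------------------------------------------------------------------
# Duplication-mode classification
# ---------------------------------------------------------------------------

@dataclass
class _PairEvidence:
    pair: HomologPair
    mode: str
    evidence: str


def classify_duplications(
    family_pairs: list[HomologPair],
    blocks: list[CollinearBlock],
    ranks: dict[str, tuple[str, int]],
    outgroup_blocks: list[CollinearBlock],
    family_genes: list[str],
    proximal_window: int = 10,
    wgd_envelope: bool = False,
) -> list[DuplicationCall]:
    """Classify each family gene's duplication mode.

    Priority per pair: WGD (anchor of an intra-genome block; with
    ``wgd_envelope`` also any pair inside a block's rank envelope on both
    sides), then TD (|rank gap| = 1, same chromosome), PD (gap <= window),
    TRD (exactly one member is an ancestral locus — an anchor in any block
    against the outgroup — and the pair is in no intra-genome block), else
    DSD.  A gene takes the mode of its highest-priority pair; family genes
    with no pair are singletons.
    """
    anchor_pairs = {key for b in blocks for key in b.anchor_set}
    ancestral = {g for b in outgroup_blocks for p in b.anchors
                 for g in (p.gene_a, p.gene_b)}

    envelopes = []
    if wgd_envelope:
        for b in blocks:
            ras = [ranks[p.gene_a][1] for p in b.anchors]
            rbs = [ranks[p.gene_b][1] for p in b.anchors]
            envelopes.append(
                (b.chrom_a, min(ras), max(ras), b.chrom_b, min(rbs), max(rbs))
            )

    def pair_mode(p: HomologPair) -> _PairEvidence:
        if p.gene_a not in ranks or p.gene_b not in ranks:
            raise ValidationError(f"gene missing rank: {p.gene_a} or {p.gene_b}")
        ca, ra = ranks[p.gene_a]
        cb, rb = ranks[p.gene_b]
        if (p.gene_a, p.gene_b) in anchor_pairs:
            return _PairEvidence(p, "WGD", "block anchor")
        if wgd_envelope:
            for eca, lo_a, hi_a, ecb, lo_b, hi_b in envelopes:
                in_a = ca == eca and lo_a <= ra <= hi_a
                in_b = cb == ecb and lo_b <= rb <= hi_b
                rev_a = ca == ecb and lo_b <= ra <= hi_b
                rev_b = cb == eca and lo_a <= rb <= hi_a
                if (in_a and in_b) or (rev_a and rev_b):
                    return _PairEvidence(p, "WGD", "block envelope")
        if ca == cb:
            gap = abs(ra - rb)
            if gap == 1:
                return _PairEvidence(p, "TD", "adjacent ranks")
            if 1 < gap <= proximal_window:
                return _PairEvidence(p, "PD", f"rank gap {gap}")
        n_ancestral = (p.gene_a in ancestral) + (p.gene_b in ancestral)
        if n_ancestral == 1:
            novel = p.gene_b if p.gene_a in ancestral else p.gene_a
            return _PairEvidence(p, "TRD", f"novel locus {novel}")
        return _PairEvidence(p, "DSD", "no positional signature")

    priority = {m: i for i, m in enumerate(("WGD", "TD", "PD", "TRD", "DSD"))}
    best: dict[str, _PairEvidence] = {}
    for p in family_pairs:
        ev = pair_mode(p)
        for g in (p.gene_a, p.gene_b):
            cur = best.get(g)
            if cur is None or priority[ev.mode] < priority[cur.mode]:
                best[g] = ev

    calls = []
    for g in sorted(family_genes):
        ev = best.get(g)
        if ev is None:
            calls.append(DuplicationCall(gene_id=g, mode="SINGLETON"))
        else:
            partner = ev.pair.gene_b if ev.pair.gene_a == g else ev.pair.gene_a
            calls.append(
                DuplicationCall(gene_id=g, mode=ev.mode, partner=partner,
                                evidence=ev.evidence)
            )
    return calls


def build_cnv_matrix(genes: pd.DataFrame) -> pd.DataFrame:
    """Copy-number matrix: ortholog_group x genome counts of family members.

    ``genes`` needs columns gene_id, genome, family, ortholog_group; rows
    with family 'none' are ignored.  Groups absent from a genome count 0.
    """
    fam = genes[genes["family"] != "none"]
    cnv = (
        fam.groupby(["ortholog_group", "genome"], sort=True)
        .size()
        .unstack(fill_value=0)
    )
    cnv.index.name = "ortholog_group"
    return cnv
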