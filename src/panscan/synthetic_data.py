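"""Synthetic multi-genome kinase-family data with planted ground truth.

This generator emulates the statistical structure of a genus-wide kinase
gene-family study: several diploid genomes plus an allotetraploid (two
subgenomes) and an outgroup, each carrying the same ancestral gene order;
kinase-family proteins with planted domain layouts; duplication events of
each mode planted so that their definitional signatures hold on the emitted
gene-order and homology tables; transcript truncation variants realizing
requested splice-consequence types; and FPKM tables with planted
subgenome-bias categories under multiplicative log-normal noise.

Every planted feature is recorded in truth tables, and every generated
protein is re-scanned at generation time so that the built-in domain
scanners reproduce the planted layout exactly (linkers that would create
accidental motifs are resampled).  Identical configurations (including the
seed) produce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    ConfigError,
    ExpressionMatrix,
    GeneRecord,
    GenomeID,
    ProteinRecord,
    TranscriptModel,
    assign_order_ranks,
    write_fasta,
    write_gtf_transcripts,
)
from .domain_architecture import (
    Architecture,
    PS00018,
    CA_LOOP_LENGTH,
    COORDINATING_POSITIONS,
    build_architecture,
    scan_protein,
)

__all__ = [
    "ArchitectureSpec",
    "GenomeSpec",
    "DuplicationEvent",
    "SimConfig",
    "SyntheticDataset",
    "generate_protein",
    "generate_genome_set",
    "generate_heb_dataset",
    "generate_transcript_variants",
    "simulate",
    "DEFAULT_FAMILY_COUNTS",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Cultivated-rice-like family composition (one genome's counts).
DEFAULT_FAMILY_COUNTS = {"CCaMK": 1, "CPK": 29, "CRK": 5, "PEPRK": 2, "PPCK": 3}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArchitectureSpec:
    """A planted protein layout: kinase completeness, per-EF Ca-site flags,
    and whether an N-myristoylation site is planted."""

    kinase: str = "complete"            # 'complete' | 'incomplete' | 'absent'
    ef_ca: tuple[bool, ...] = ()
    myristoylated: bool = False
    c_extension: int = 0                # extra C-terminal residues

    def __post_init__(self) -> None:
        if len(self.ef_ca) > 6:
            raise ConfigError("layouts with more than 6 EF-hands are not supported")
        if self.kinase not in ("complete", "incomplete", "absent"):
            raise ConfigError(f"bad kinase state {self.kinase!r}")

    @property
    def architecture(self) -> Architecture:
        flags = tuple(self.ef_ca)
        if self.kinase != "absent" and len(flags) >= 2:
            lobes = tuple("C" if i >= len(flags) - 2 else "N"
                          for i in range(len(flags)))
        else:
            lobes = ("none",) * len(flags)
        return Architecture(kinase_state=self.kinase, ef_hands=flags, lobes=lobes)


#: Canonical layout per family.
DEFAULT_TEMPLATES = {
    "CCaMK": ArchitectureSpec(ef_ca=(True, True, True)),
    "CPK": ArchitectureSpec(ef_ca=(True, True, True, True), myristoylated=True),
    "CRK": ArchitectureSpec(ef_ca=(False,), myristoylated=True),
    "PEPRK": ArchitectureSpec(c_extension=120),
    "PPCK": ArchitectureSpec(),
}

#: Group-level layout departures from the family canon (minority variants
#: mirroring the kinds of diversity seen in real CPK families: a three-EF
#: pair with the Ca-site confined to the C-lobe, and four-EF groups with a
#: degenerate N-lobe site).
DEFAULT_GROUP_LAYOUTS = {
    "CPK7": ArchitectureSpec(ef_ca=(False, False, True), myristoylated=True),
    "CPK23": ArchitectureSpec(ef_ca=(False, False, True), myristoylated=True),
    "CPK3": ArchitectureSpec(ef_ca=(False, True, True, True), myristoylated=True),
    "CPK16": ArchitectureSpec(ef_ca=(False, True, True, True), myristoylated=True),
    "CPK29": ArchitectureSpec(ef_ca=(False, True, True, True), myristoylated=True),
    "CRK1": ArchitectureSpec(),   # kinase-only CRKs
    "CRK2": ArchitectureSpec(),
    "CRK3": ArchitectureSpec(),
    "CRK5": ArchitectureSpec(),
    "CRK4": ArchitectureSpec(ef_ca=(False,), myristoylated=True),
}


@dataclass(frozen=True)
class GenomeSpec:
    genome: GenomeID
    n_chromosomes: int = 4
    genes_per_chromosome: int = 130


@dataclass(frozen=True)
class DuplicationEvent:
    ortholog_group: str
    genome: str        # genome label (species or species-subgenome)
    mode: str          # WGD | TD | PD | TRD | DSD


def _default_genomes() -> tuple[GenomeSpec, ...]:
    return (
        GenomeSpec(GenomeID("Gsat")),                # cultivated-like diploid
        GenomeSpec(GenomeID("Gwild")),               # wild diploid with events
        GenomeSpec(GenomeID("Gtetra", "BB", "subgenome_of_allotetraploid")),
        GenomeSpec(GenomeID("Gtetra", "CC", "subgenome_of_allotetraploid")),
    )


def _default_events() -> tuple[DuplicationEvent, ...]:
    return (
        DuplicationEvent("CRK2", "Gwild", "WGD"),
        DuplicationEvent("CPK12", "Gwild", "TD"),
        DuplicationEvent("CPK15", "Gwild", "PD"),
        DuplicationEvent("CPK29", "Gwild", "TRD"),
        DuplicationEvent("CPK26", "Gwild", "DSD"),
        DuplicationEvent("CPK7", "Gtetra-BB", "WGD"),
        DuplicationEvent("CPK21", "Gtetra-BB", "TD"),
        DuplicationEvent("PPCK2", "Gtetra-BB", "TRD"),
    )


def _default_as_requests() -> dict[str, tuple[str, ...]]:
    return {
        "CPK1": ("CANONICAL", "T1", "T2", "T3", "T4", "T5", "T6", "T7", "T8", "T9"),
        "CPK2": ("CANONICAL", "T2", "T4", "T9"),
        "CCaMK1": ("CANONICAL", "T5", "T7", "T8"),
    }


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset."""

    seed: int = 0
    genomes: tuple[GenomeSpec, ...] = field(default_factory=_default_genomes)
    outgroup: GenomeSpec = field(
        default_factory=lambda: GenomeSpec(
            GenomeID("Lout", ploidy_role="outgroup")
        )
    )
    family_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_COUNTS)
    )
    templates: dict[str, ArchitectureSpec] = field(
        default_factory=lambda: dict(DEFAULT_TEMPLATES)
    )
    group_layouts: dict[str, ArchitectureSpec] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_LAYOUTS)
    )
    duplication_events: tuple[DuplicationEvent, ...] = field(
        default_factory=_default_events
    )
    wgd_block_anchor_count: int = 8
    as_requests: dict[str, tuple[str, ...]] = field(
        default_factory=_default_as_requests
    )
    tissues: tuple[str, ...] = ("root", "stem", "leaf", "panicle")
    n_replicates: int = 2
    p_dom: float = 0.9
    expression_noise_sd: float = 0.2
    heb_category_weights: dict[str, float] = field(
        default_factory=lambda: {
            "BALANCED": 0.5, "DOM_A": 0.2, "DOM_B": 0.2, "NOT_EXPRESSED": 0.1,
        }
    )
    # Sequence evolution rates (substitutions per mutable site).
    group_divergence: float = 0.08
    genome_divergence: float = 0.02
    duplicate_divergence: float = 0.01

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.family_counts.values()):
            raise ConfigError("family counts must be >= 0")
        if not 0.5 < self.p_dom <= 1.0:
            raise ConfigError("p_dom must be in (0.5, 1]")
        if self.wgd_block_anchor_count < 5:
            raise ConfigError("wgd_block_anchor_count must be >= 5")
        if self.expression_noise_sd < 0:
            raise ConfigError("expression noise sd must be >= 0")
        modes_by_group: dict[str, set[str]] = {}
        for ev in self.duplication_events:
            if ev.mode not in ("WGD", "TD", "PD", "TRD", "DSD"):
                raise ConfigError(f"unknown duplication mode {ev.mode!r}")
            modes_by_group.setdefault(ev.ortholog_group, set()).add(ev.mode)

    def group_names(self) -> list[str]:
        out = []
        for family in ("CCaMK", "CPK", "CRK", "PEPRK", "PPCK"):
            for i in range(self.family_counts.get(family, 0)):
                out.append(f"{family}{i + 1}")
        return out

    def layout_for(self, group: str, family: str) -> ArchitectureSpec:
        return self.group_layouts.get(group, self.templates[family])


# ---------------------------------------------------------------------------
# Protein construction
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(AA20[i] for i in rng.integers(0, 20, size=n))


def _sample_loop(rng: np.random.Generator, ca_site: bool) -> str:
    """A 13-residue EF loop: strict calcium-loop match, or (degenerate) the
    same with 1-2 coordinating positions flipped to excluded residues."""
    loop = []
    for el in PS00018.elements:
        reps = el.min_n
        for _ in range(reps):
            if el.kind in ("literal", "allowed"):
                pool = sorted(el.residues)
            elif el.kind == "forbidden":
                pool = sorted(set(AA20) - el.residues)
            else:
                pool = list(AA20)
            loop.append(pool[rng.integers(0, len(pool))])
    if not ca_site:
        # Flip coordinating positions 3/5/9 (keeping both anchors) to
        # residues their classes exclude.
        flippable = [3, 5, 9]
        k = int(rng.integers(1, 3))
        for pos in sorted(rng.choice(flippable, size=k, replace=False)):
            el = PS00018.elements[pos - 1]
            pool = sorted(set(AA20) - el.residues)
            loop[pos - 1] = pool[rng.integers(0, len(pool))]
    return "".join(loop)


@dataclass
class ProteinTruth:
    """Planted layout and span bookkeeping for one generated protein."""

    layout: ArchitectureSpec
    anchor_spans: list[tuple[int, int]]      # walker/HRD/DFG spans present
    kinase_core_end: int                     # end of last planted anchor
    ef_spans: list[tuple[int, int]]
    mutable: np.ndarray                      # bool mask of linker positions

    @property
    def architecture(self) -> Architecture:
        return self.layout.architecture


def _build_sequence(
    layout: ArchitectureSpec,
    rng: np.random.Generator,
    bank: dict[str, str] | None = None,
) -> tuple[str, ProteinTruth, dict[str, str]]:
    """Assemble a sequence for ``layout``.

    ``bank`` maps named linker slots to sequences; slots present in the bank
    are reused (so related proteins share their linkers and stay alignable),
    missing slots are drawn fresh and recorded.
    """
    bank = dict(bank or {})
    parts: list[str] = []
    protected: list[tuple[int, int]] = []
    pos = 0

    def add(segment: str, protect: bool = False) -> tuple[int, int]:
        nonlocal pos
        parts.append(segment)
        span = (pos, pos + len(segment))
        if protect:
            protected.append(span)
        pos += len(segment)
        return span

    def linker(slot: str, lo: int, hi: int, extra: int = 0) -> tuple[int, int]:
        if slot not in bank:
            bank[slot] = _random_seq(rng, int(rng.integers(lo, hi)) + extra)
        return add(bank[slot])

    if layout.myristoylated:
        add("MGNACS", protect=True)   # Met-Gly start satisfying the consensus
    else:
        add("MS", protect=True)
    linker("nterm", 15, 31)

    anchor_spans: list[tuple[int, int]] = []
    kinase_core_end = 0
    if layout.kinase != "absent":
        linker("prewalker", 8, 15)
        walker = add("AYIK", protect=True)
        linker("walker_hrd", 95, 111)
        hrd = add("HRD", protect=True)
        anchor_spans = [walker, hrd]
        if layout.kinase == "complete":
            linker("hrd_dfg", 80, 96)
            dfg = add("DFG", protect=True)
            anchor_spans.append(dfg)
        kinase_core_end = anchor_spans[-1][1]
        linker("postkinase", 10, 21)

    ef_spans: list[tuple[int, int]] = []
    if layout.ef_ca:
        # Keep the first loop clear of the padded kinase span.
        linker("pre_ef", 45, 61)
        for i, ca in enumerate(layout.ef_ca):
            if i:
                linker(f"spacer{i}", 10, 21)
            ef_spans.append(add(_sample_loop(rng, ca), protect=True))

    linker("cterm", 8, 16, extra=layout.c_extension)

    seq = "".join(parts)
    mutable = np.ones(len(seq), dtype=bool)
    for s, e in protected:
        mutable[s:e] = False
    truth = ProteinTruth(
        layout=layout,
        anchor_spans=anchor_spans,
        kinase_core_end=kinase_core_end,
        ef_spans=ef_spans,
        mutable=mutable,
    )
    return seq, truth, bank


def _scan_matches(seq: str, expected: Architecture) -> bool:
    prot = ProteinRecord(protein_id="probe", sequence=seq)
    arch = build_architecture(scan_protein(prot), len(seq))
    return arch.signature == expected.signature


def generate_protein(
    family: str,
    layout: ArchitectureSpec,
    rng: np.random.Generator,
    protein_id: str = "synthetic",
    max_tries: int = 60,
    bank: dict[str, str] | None = None,
) -> tuple[ProteinRecord, ProteinTruth]:
    """Generate one protein realizing ``layout`` exactly.

    The sequence is assembled from planted motifs and random linkers; it is
    re-scanned and resampled until the built-in scanners reproduce the
    planted architecture (accidental motifs in linkers are thereby ruled
    out, keeping the planting noise-free).  With a linker ``bank`` the
    protein shares its linkers with others built from the same bank.
    """
    rec, truth, _ = _generate_with_bank(layout, rng, protein_id, max_tries, bank)
    return rec, truth


def _generate_with_bank(
    layout: ArchitectureSpec,
    rng: np.random.Generator,
    protein_id: str,
    max_tries: int = 60,
    bank: dict[str, str] | None = None,
) -> tuple[ProteinRecord, ProteinTruth, dict[str, str]]:
    expected = layout.architecture
    for attempt in range(max_tries):
        # If a fixed bank keeps failing (an accidental motif at a segment
        # boundary), fall back to fresh linkers after a few tries.
        use_bank = bank if attempt < max_tries // 2 else None
        seq, truth, bank_out = _build_sequence(layout, rng, use_bank)
        if _scan_matches(seq, expected):
            return ProteinRecord(protein_id=protein_id, sequence=seq), truth, bank_out
    raise RuntimeError(f"could not realize layout for {protein_id}")


def _mutate(
    seq: str,
    truth: ProteinTruth,
    rate: float,
    rng: np.random.Generator,
    max_tries: int = 30,
) -> str:
    """Substitute ~``rate`` of linker positions, preserving the planted
    architecture (verified by re-scan; offending draws are resampled)."""
    if rate <= 0:
        return seq
    idx = np.flatnonzero(truth.mutable)
    n_mut = int(round(rate * len(idx)))
    if n_mut == 0:
        return seq
    expected = truth.architecture
    for _ in range(max_tries):
        chars = list(seq)
        for i in rng.choice(idx, size=n_mut, replace=False):
            cur = chars[i]
            pool = AA20.replace(cur, "")
            chars[i] = pool[rng.integers(0, len(pool))]
        cand = "".join(chars)
        if _scan_matches(cand, expected):
            return cand
    return seq


# ---------------------------------------------------------------------------
# Genome sets with planted duplication events
# ---------------------------------------------------------------------------

@dataclass
class GenomeSetBundle:
    genes: pd.DataFrame                  # gene-order table incl. order_rank
    homology: pd.DataFrame               # gene_a, gene_b, score, scope
    proteins: list[ProteinRecord]        # family proteins, all genomes
    protein_truth: dict[str, ProteinTruth]
    seeds: dict[str, list[ProteinRecord]]
    duplication_truth: pd.DataFrame      # genome, group, mode, gene, partner
    outgroup_label: str

    def ranks(self) -> dict[str, tuple[str, int]]:
        return {
            r.gene_id: (r.chromosome, int(r.order_rank))
            for r in self.genes.itertuples()
        }


def _slot_positions(n_groups_on_chrom: int, genes_per_chrom: int, margin: int):
    stride = max((genes_per_chrom - 2 * margin) // max(n_groups_on_chrom, 1), 1)
    return [margin + j * stride for j in range(n_groups_on_chrom)]


def generate_genome_set(config: SimConfig) -> GenomeSetBundle:
    """Emit gene orders, homology pairs, family proteins and truth tables.

    Every genome shares one ancestral gene order (lightly perturbed by
    adjacent background swaps); each requested duplication event is planted
    so its definitional signature holds: WGD inside a planted collinear
    block with ``wgd_block_anchor_count`` flanking anchors, TD at adjacent
    rank, PD within the proximal window, TRD at a novel locus with its mate
    keeping outgroup collinearity, and DSD with both copies relocated off
    their ancestral locus.  The outgroup genome keeps the unduplicated
    ancestral order.
    """
    rng = np.random.default_rng(config.seed)
    groups = config.group_names()
    specs = list(config.genomes) + [config.outgroup]
    labels = [s.genome.label for s in specs]
    if len(set(labels)) != len(labels):
        raise ConfigError("duplicate genome labels")
    by_label = dict(zip(labels, specs))
    for ev in config.duplication_events:
        if ev.genome not in by_label or by_label[ev.genome] is config.outgroup:
            raise ConfigError(f"duplication event in unknown genome {ev.genome!r}")
        if ev.ortholog_group not in groups:
            raise ConfigError(f"unknown ortholog group {ev.ortholog_group!r}")

    n_chrom = min(s.n_chromosomes for s in specs)
    if n_chrom < 2:
        raise ConfigError("need at least 2 chromosomes to plant relocations")
    gpc = min(s.genes_per_chromosome for s in specs)
    margin = config.wgd_block_anchor_count // 2 + 4

    # Ancestral order: background ortholog groups with family groups at
    # evenly spaced slots.
    family_of = {}
    for g in groups:
        family_of[g] = "".join(c for c in g if not c.isdigit())
    per_chrom_groups = [groups[c::n_chrom] for c in range(n_chrom)]
    ancestral: list[list[str]] = []
    for c in range(n_chrom):
        chrom_groups = per_chrom_groups[c]
        if len(chrom_groups) * max(
            (gpc - 2 * margin) // max(len(chrom_groups), 1), 1
        ) + margin > gpc:
            raise ConfigError(
                "chromosome too short to host the requested family groups "
                "and block margins"
            )
        order = [f"BG{c}_{i}" for i in range(gpc)]
        for slot, grp in zip(
            _slot_positions(len(chrom_groups), gpc, margin), chrom_groups
        ):
            order[slot] = grp
        ancestral.append(order)

    # Family protein ancestry: one template (and linker bank) per family,
    # then per-group proteins sharing the bank so families stay alignable.
    template_prot: dict[str, tuple[str, ProteinTruth, dict[str, str]]] = {}
    for family in ("CCaMK", "CPK", "CRK", "PEPRK", "PPCK"):
        if config.family_counts.get(family, 0) <= 0:
            continue
        rec, truth, bank = _generate_with_bank(
            config.templates[family], rng, protein_id=f"seed_{family}"
        )
        template_prot[family] = (rec.sequence, truth, bank)
    group_prot: dict[str, tuple[str, ProteinTruth]] = {}
    for grp in groups:
        family = family_of[grp]
        layout = config.layout_for(grp, family)
        _, _, bank = template_prot[family]
        rec, truth, _ = _generate_with_bank(layout, rng, grp, bank=bank)
        seq = _mutate(rec.sequence, truth, config.group_divergence, rng)
        group_prot[grp] = (seq, truth)

    gene_rows: list[dict] = []
    hom_rows: list[dict] = []
    proteins: list[ProteinRecord] = []
    protein_truth: dict[str, ProteinTruth] = {}
    dup_rows: list[dict] = []

    events_by_genome: dict[str, list[DuplicationEvent]] = {}
    for ev in config.duplication_events:
        events_by_genome.setdefault(ev.genome, []).append(ev)

    outgroup_label = config.outgroup.genome.label
    outgroup_gene: dict[str, str] = {}

    def gid(label: str, group: str, suffix: str = "") -> str:
        return f"{label}_{group}{suffix}"

    for spec in specs:
        label = spec.genome.label
        is_outgroup = spec is config.outgroup
        # Per-chromosome ordered lists of (gene_id, group, family, origin).
        chrom_orders: list[list[tuple[str, str, str]]] = []
        for c in range(n_chrom):
            entries = []
            for grp in ancestral[c]:
                fam = family_of.get(grp, "none")
                entries.append((gid(label, grp), grp, fam))
            chrom_orders.append(entries)

        # Light per-genome perturbation: a few adjacent background swaps.
        if not is_outgroup:
            for c in range(n_chrom):
                order = chrom_orders[c]
                for _ in range(3):
                    i = int(rng.integers(1, len(order) - 2))
                    if order[i][2] == "none" and order[i + 1][2] == "none":
                        order[i], order[i + 1] = order[i + 1], order[i]

        # Plant duplication events.
        for ev in events_by_genome.get(label, []) if not is_outgroup else []:
            grp = ev.ortholog_group
            # Locate the original.
            loc = next(
                (c, i)
                for c, order in enumerate(chrom_orders)
                for i, e in enumerate(order)
                if e[1] == grp
            )
            c, i = loc
            order = chrom_orders[c]
            orig_id = order[i][0]
            dup_id = gid(label, grp, "d")
            fam = family_of[grp]
            other_c = (c + 1) % n_chrom

            if ev.mode == "TD":
                order.insert(i + 1, (dup_id, grp, fam))
            elif ev.mode == "PD":
                delta = int(rng.integers(3, 11))
                order.insert(min(i + delta, len(order)), (dup_id, grp, fam))
            elif ev.mode == "WGD":
                w = config.wgd_block_anchor_count
                before = w // 2
                after = w - before
                window = order[i - before : i + after + 1]
                if any(e[2] != "none" and e[1] != grp for e in window):
                    raise ConfigError(
                        f"WGD window around {grp} overlaps another family gene"
                    )
                segment = []
                for src_id, src_grp, src_fam in window:
                    copy_grp = src_grp
                    copy_id = dup_id if src_grp == grp else src_id + "w"
                    segment.append((copy_id, copy_grp, src_fam))
                    hom_rows.append(
                        {"gene_a": min(src_id, copy_id),
                         "gene_b": max(src_id, copy_id),
                         "score": 900.0, "scope": "intra", "genome": label}
                    )
                chrom_orders[other_c].extend(segment)
            elif ev.mode == "TRD":
                chrom_orders[other_c].append((dup_id, grp, fam))
            elif ev.mode == "DSD":
                # Relocate the original off its ancestral locus too, so
                # neither copy keeps outgroup collinearity.
                del order[i]
                chrom_orders[other_c].append((orig_id, grp, fam))
                chrom_orders[(c + 2) % n_chrom if n_chrom > 2 else c].append(
                    (dup_id, grp, fam)
                )
            if ev.mode != "WGD":
                hom_rows.append(
                    {"gene_a": min(orig_id, dup_id),
                     "gene_b": max(orig_id, dup_id),
                     "score": 950.0, "scope": "intra", "genome": label}
                )
            dup_rows.append(
                {"genome": label, "ortholog_group": grp, "mode": ev.mode,
                 "gene": orig_id, "partner": dup_id}
            )

        # Emit gene records with coordinates realizing the final order, and
        # family proteins.
        for c, order in enumerate(chrom_orders):
            chrom = f"{label}.c{c + 1}"
            start = 1000
            for gene_id, grp, fam in order:
                length = int(rng.integers(1200, 2400))
                gene_rows.append(
                    {
                        "gene_id": gene_id,
                        "genome": label,
                        "subgenome": spec.genome.subgenome,
                        "chromosome": chrom,
                        "start": start,
                        "end": start + length,
                        "strand": "+" if rng.random() < 0.5 else "-",
                        "family": fam,
                        "ortholog_group": grp,
                    }
                )
                start += length + int(rng.integers(500, 1500))
                if is_outgroup:
                    outgroup_gene[grp] = gene_id
                if fam != "none":
                    base_seq, base_truth = group_prot[grp]
                    rate = (
                        config.genome_divergence
                        if not gene_id.endswith(("d",))
                        else config.genome_divergence + config.duplicate_divergence
                    )
                    seq = _mutate(base_seq, base_truth, rate, rng)
                    proteins.append(
                        ProteinRecord(
                            protein_id=gene_id, gene_id=gene_id, sequence=seq
                        )
                    )
                    protein_truth[gene_id] = base_truth

    # Cross-genome homology versus the outgroup (for ancestral-locus tests).
    for row in gene_rows:
        if row["genome"] == outgroup_label:
            continue
        grp = row["ortholog_group"]
        og = outgroup_gene.get(grp)
        if og is None:
            continue
        hom_rows.append(
            {"gene_a": min(row["gene_id"], og),
             "gene_b": max(row["gene_id"], og),
             "score": 500.0, "scope": "outgroup", "genome": row["genome"]}
        )

    genes = assign_order_ranks(pd.DataFrame(gene_rows))
    homology = pd.DataFrame(hom_rows).drop_duplicates(
        subset=["gene_a", "gene_b"]
    ).reset_index(drop=True)
    seeds = {
        fam: [ProteinRecord(protein_id=f"seed_{fam}", sequence=seq)]
        for fam, (seq, _, _) in template_prot.items()
    }
    return GenomeSetBundle(
        genes=genes,
        homology=homology,
        proteins=proteins,
        protein_truth=protein_truth,
        seeds=seeds,
        duplication_truth=pd.DataFrame(dup_rows),
        outgroup_label=outgroup_label,
    )


# ---------------------------------------------------------------------------
# Expression with planted homoeolog bias
# ---------------------------------------------------------------------------

def generate_heb_dataset(
    n_pairs: int | None = None,
    *,
    pairs: pd.DataFrame | None = None,
    truth: pd.DataFrame | None = None,
    tissues: tuple[str, ...] = ("root", "stem", "leaf", "panicle"),
    p_dom: float = 0.9,
    noise_sd: float = 0.2,
    n_replicates: int = 2,
    species: str = "synthetic4x",
    category_weights: dict[str, float] | None = None,
    rng: np.random.Generator | int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """An FPKM matrix with planted homoeolog-bias categories.

    Either ``n_pairs`` (pairs are invented) or an explicit ``pairs`` table
    (pair_id, gene_a, gene_b) must be given.  Planted categories come from
    ``truth`` (pair_id, tissue, category) or are drawn from
    ``category_weights``.  For a dominant pair at total expression T (drawn
    log-uniform in [2, 200]) the dominant homoeolog gets T*p_dom and the
    other T*(1-p_dom), each replicate multiplied by log-normal noise
    exp(N(0, noise_sd)); balanced pairs use p=0.5; unexpressed pairs draw
    every replicate uniform in [0, 0.5].
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if noise_sd < 0:
        raise ConfigError("noise sd must be >= 0")
    if not 0.5 < p_dom <= 1.0:
        raise ConfigError("p_dom must be in (0.5, 1]")
    if pairs is None:
        if n_pairs is None:
            raise ConfigError("give n_pairs or pairs")
        width = len(str(max(n_pairs, 1)))
        pairs = pd.DataFrame(
            {
                "pair_id": [f"P{i:0{width}d}" for i in range(n_pairs)],
                "gene_a": [f"P{i:0{width}d}_A" for i in range(n_pairs)],
                "gene_b": [f"P{i:0{width}d}_B" for i in range(n_pairs)],
            }
        )
    weights = category_weights or {
        "BALANCED": 0.5, "DOM_A": 0.2, "DOM_B": 0.2, "NOT_EXPRESSED": 0.1,
    }
    cats = sorted(weights)
    probs = np.array([weights[c] for c in cats], dtype=float)
    probs /= probs.sum()

    truth_map: dict[tuple[str, str], str] = {}
    if truth is not None:
        for r in truth.itertuples():
            truth_map[(str(r.pair_id), str(r.tissue))] = str(r.category)

    samples = [
        (f"{species}_{t}_r{i + 1}", t, i + 1)
        for t in tissues
        for i in range(n_replicates)
    ]
    sample_meta = pd.DataFrame(
        [{"sample": s, "species": species, "tissue": t, "replicate": r}
         for s, t, r in samples]
    ).set_index("sample")

    genes = list(pairs["gene_a"]) + list(pairs["gene_b"])
    values = pd.DataFrame(
        0.0, index=pd.Index(genes, name="gene_id"),
        columns=[s for s, _, _ in samples],
    )
    truth_rows = []
    for pr in pairs.itertuples():
        for t in tissues:
            cat = truth_map.get((str(pr.pair_id), t))
            if cat is None:
                cat = cats[int(rng.choice(len(cats), p=probs))]
            cols = [s for s, tt, _ in samples if tt == t]
            if cat == "NOT_EXPRESSED":
                for g in (pr.gene_a, pr.gene_b):
                    values.loc[g, cols] = rng.uniform(0.0, 0.5, size=len(cols))
            else:
                total = float(np.exp(rng.uniform(np.log(2.0), np.log(200.0))))
                share = {
                    "BALANCED": (0.5, 0.5),
                    "DOM_A": (p_dom, 1.0 - p_dom),
                    "DOM_B": (1.0 - p_dom, p_dom),
                }[cat]
                for g, frac in zip((pr.gene_a, pr.gene_b), share):
                    eps = (
                        np.exp(rng.normal(0.0, noise_sd, size=len(cols)))
                        if noise_sd > 0
                        else np.ones(len(cols))
                    )
                    values.loc[g, cols] = total * frac * eps
            truth_rows.append(
                {"pair_id": pr.pair_id, "tissue": t, "category": cat}
            )
    matrix = ExpressionMatrix(values=values, sample_meta=sample_meta)
    return matrix, pairs.copy(), pd.DataFrame(truth_rows)


def _atlas_matrix(
    genes: pd.DataFrame,
    species: str,
    tissues: tuple[str, ...],
    n_replicates: int,
    noise_sd: float,
    rng: np.random.Generator,
    silent_genes: set[str] = frozenset(),
    root_dominant_families: tuple[str, ...] = ("CCaMK",),
) -> ExpressionMatrix:
    """Baseline expression atlas for one species' family genes.

    Genes in root-dominant families get a 10x root boost; ``silent_genes``
    stay below the expression threshold everywhere (a pseudogenization
    signal)."""
    fam_genes = genes[(genes["genome"].str.startswith(species))
                      & (genes["family"] != "none")]
    samples = [
        (f"{species}_{t}_r{i + 1}", t, i + 1)
        for t in tissues
        for i in range(n_replicates)
    ]
    meta = pd.DataFrame(
        [{"sample": s, "species": species, "tissue": t, "replicate": r}
         for s, t, r in samples]
    ).set_index("sample")
    values = pd.DataFrame(
        0.0, index=pd.Index(list(fam_genes["gene_id"]), name="gene_id"),
        columns=[s for s, _, _ in samples],
    )
    for row in fam_genes.itertuples():
        if row.gene_id in silent_genes:
            for s, t, _ in samples:
                values.loc[row.gene_id, s] = float(rng.uniform(0.0, 0.3))
            continue
        base = {
            t: float(np.exp(rng.uniform(np.log(1.0), np.log(60.0))))
            for t in tissues
        }
        if row.family in root_dominant_families and "root" in base:
            base["root"] *= 10.0
        for s, t, _ in samples:
            eps = float(np.exp(rng.normal(0.0, noise_sd))) if noise_sd > 0 else 1.0
            values.loc[row.gene_id, s] = base[t] * eps
    return ExpressionMatrix(values=values, sample_meta=meta)


# ---------------------------------------------------------------------------
# Transcript truncation variants
# ---------------------------------------------------------------------------

_AS_MIN_EF = {
    "T1": 4, "T2": 3, "T3": 2, "T4": 1, "T5": 0,
    "T6": 4, "T7": 3, "T8": 2, "T9": 1, "CANONICAL": 0,
}
_AS_KEEP_EF = {"T1": 3, "T2": 2, "T3": 1, "T4": 0}
_AS_ONLY_EF = {"T6": 4, "T7": 3, "T8": 2, "T9": 1}


def _mrna_to_genomic(
    exons_53: list[tuple[int, int]], strand: str, a: int, b: int
) -> list[tuple[int, int]]:
    """Map the transcript-relative nt interval [a, b) to genomic intervals."""
    out = []
    off = 0
    for s, e in exons_53:
        length = e - s
        lo, hi = max(a - off, 0), min(b - off, length)
        if lo < hi:
            if strand == "+":
                out.append((s + lo, s + hi))
            else:
                out.append((e - hi, e - lo))
        off += length
    return sorted(out)


def generate_transcript_variants(
    gene: GeneRecord,
    layout: ArchitectureSpec,
    types: list[str],
    rng: np.random.Generator,
    max_tries: int = 40,
) -> tuple[list[TranscriptModel], dict[str, ProteinRecord], pd.DataFrame]:
    """Transcript variants of one gene realizing the requested splice types.

    The canonical protein realizes ``layout``; each requested type yields a
    transcript whose translated protein has exactly that absolute domain
    content (C-terminal truncations for fewer EF-hands or a broken kinase,
    N-terminal truncations for EF-only variants).  Exon/CDS structures
    differ from the canonical transcript by truncated terminal exons.
    """
    if layout.kinase != "complete" or not 3 <= len(layout.ef_ca) <= 4:
        raise ConfigError(
            "canonical layout must have a complete kinase and 3-4 EF-hands"
        )
    n_ef = len(layout.ef_ca)
    for t in types:
        if t not in _AS_MIN_EF:
            raise ConfigError(f"unknown splice-consequence type {t!r}")
        if _AS_MIN_EF[t] > n_ef:
            raise ConfigError(
                f"type {t} incompatible with a {n_ef}-EF canonical layout"
            )
        if t in ("T1", "T2", "T3") and _AS_KEEP_EF[t] >= n_ef:
            raise ConfigError(
                f"type {t} incompatible with a {n_ef}-EF canonical layout"
            )

    for _ in range(max_tries):
        canon, truth = generate_protein(
            gene.family if gene.family != "none" else "CPK",
            layout, rng, protein_id=f"{gene.gene_id}.t1",
        )
        seq = canon.sequence
        variants: dict[str, str] = {}
        ok = True
        for t in types:
            if t == "CANONICAL":
                variants[t] = seq
            elif t in _AS_KEEP_EF:
                k = _AS_KEEP_EF[t]
                cut = (
                    truth.ef_spans[k - 1][1] + 3
                    if k >= 1
                    else truth.kinase_core_end + 5
                )
                variants[t] = seq[:cut]
            elif t == "T5":
                # Keep the Walker-lysine and catalytic anchors only.
                variants[t] = seq[: truth.anchor_spans[1][1] + 4]
            else:
                k = _AS_ONLY_EF[t]
                cut_start = (
                    truth.ef_spans[n_ef - k - 1][1]
                    if k < n_ef
                    else truth.kinase_core_end + 10
                )
                variants[t] = "M" + seq[cut_start:]
            expected = _expected_variant_arch(t, layout)
            if not _scan_matches(variants[t], expected):
                ok = False
                break
        if ok:
            break
    else:
        raise RuntimeError(f"could not realize variants for {gene.gene_id}")

    # Canonical gene model: three exons covering the CDS, 150 nt introns.
    total_nt = 3 * len(seq)
    cuts = sorted({total_nt // 3, 2 * total_nt // 3})
    lengths = np.diff([0, *cuts, total_nt])
    exons = []
    gpos = gene.start
    for L in lengths:
        exons.append((gpos, gpos + int(L)))
        gpos += int(L) + 150
    strand = gene.strand
    exons_53 = exons if strand == "+" else [e for e in reversed(exons)]

    models: list[TranscriptModel] = []
    proteins: dict[str, ProteinRecord] = {}
    truth_rows = []
    for idx, t in enumerate(types, start=1):
        tid = f"{gene.gene_id}.t{idx}"
        vseq = variants[t]
        if t in _AS_ONLY_EF:
            # N-terminal truncation: drop the 5' part of the mRNA.
            removed = len(seq) - (len(vseq) - 1)
            window = (3 * removed, total_nt)
        else:
            window = (0, 3 * len(vseq))
        cds = _mrna_to_genomic(exons_53, strand, *window)
        ex = cds if t != "CANONICAL" else [tuple(e) for e in exons]
        model = TranscriptModel(
            transcript_id=tid,
            gene_id=gene.gene_id,
            strand=strand,
            chromosome=gene.chromosome,
            exons=sorted(ex, reverse=(strand == "-")),
            cds=sorted(cds, reverse=(strand == "-")),
        )
        models.append(model)
        proteins[tid] = ProteinRecord(
            protein_id=tid, gene_id=gene.gene_id, transcript_id=tid, sequence=vseq
        )
        truth_rows.append(
            {"transcript_id": tid, "gene_id": gene.gene_id, "type": t}
        )
    return models, proteins, pd.DataFrame(truth_rows)


def _expected_variant_arch(t: str, layout: ArchitectureSpec) -> Architecture:
    n_ef = len(layout.ef_ca)
    if t == "CANONICAL":
        spec = layout
    elif t in _AS_KEEP_EF:
        spec = ArchitectureSpec(
            kinase="complete", ef_ca=layout.ef_ca[: _AS_KEEP_EF[t]]
        )
    elif t == "T5":
        spec = ArchitectureSpec(kinase="incomplete", ef_ca=())
    else:
        k = _AS_ONLY_EF[t]
        spec = ArchitectureSpec(kinase="absent", ef_ca=layout.ef_ca[n_ef - k:])
    return spec.architecture


# ---------------------------------------------------------------------------
# Whole-dataset simulation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """Everything the pipeline consumes, plus the planted truth tables."""

    config: SimConfig
    genome_set: GenomeSetBundle
    transcripts: list[TranscriptModel]
    variant_proteins: dict[str, ProteinRecord]
    as_truth: pd.DataFrame
    expression: dict[str, ExpressionMatrix]
    heb_pairs: pd.DataFrame
    heb_truth: pd.DataFrame
    heb_species: str

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        (out / "truth").mkdir(parents=True, exist_ok=True)
        gs = self.genome_set
        gs.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
        gs.homology.to_csv(out / "homology.tsv", sep="\t", index=False)
        write_fasta(gs.proteins, out / "proteins.fasta")
        write_fasta(
            [p for fam in sorted(gs.seeds) for p in gs.seeds[fam]],
            out / "seeds.fasta",
        )
        write_gtf_transcripts(self.transcripts, out / "transcripts.gtf")
        write_fasta(
            [self.variant_proteins[t] for t in sorted(self.variant_proteins)],
            out / "variant_proteins.fasta",
        )
        for species in sorted(self.expression):
            m = self.expression[species]
            m.values.to_csv(out / f"expression_{species}.tsv", sep="\t")
            m.sample_meta.to_csv(out / f"samples_{species}.tsv", sep="\t")
        self.heb_pairs.to_csv(out / "heb_pairs.tsv", sep="\t", index=False)
        gs.duplication_truth.to_csv(
            out / "truth" / "duplications.tsv", sep="\t", index=False
        )
        self.as_truth.to_csv(out / "truth" / "as_types.tsv", sep="\t", index=False)
        self.heb_truth.to_csv(out / "truth" / "heb.tsv", sep="\t", index=False)
        with open(out / "config.json", "w") as fh:
            json.dump(_config_json(self.config), fh, indent=2, default=str)


def _config_json(config: SimConfig) -> dict:
    d = asdict(config)
    d["genomes"] = [
        {"label": g.genome.label, "n_chromosomes": g.n_chromosomes,
         "genes_per_chromosome": g.genes_per_chromosome}
        for g in config.genomes
    ]
    d["outgroup"] = {"label": config.outgroup.genome.label}
    return d


def simulate(config: SimConfig | None = None) -> SyntheticDataset:
    """Run the full generator: genomes, proteins, variants, expression."""
    config = config or SimConfig()
    bundle = generate_genome_set(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    # Splice variants are planted on the first (cultivated-like) genome.
    host_label = config.genomes[0].genome.label
    genes_by_group = {
        (r.genome, r.ortholog_group): r
        for r in bundle.genes.itertuples()
        if r.family != "none"
    }
    transcripts: list[TranscriptModel] = []
    variant_proteins: dict[str, ProteinRecord] = {}
    as_rows = []
    for grp in sorted(config.as_requests):
        req = list(config.as_requests[grp])
        row = genes_by_group.get((host_label, grp))
        if row is None:
            raise ConfigError(f"splice-variant host gene {grp} not in {host_label}")
        gene = GeneRecord(
            gene_id=row.gene_id,
            genome=GenomeID(host_label),
            chromosome=row.chromosome,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            family=row.family,
            ortholog_group=row.ortholog_group,
        )
        fam = "".join(c for c in grp if not c.isdigit())
        layout = config.layout_for(grp, fam)
        models, prots, truth = generate_transcript_variants(
            gene, layout, req, rng
        )
        transcripts.extend(models)
        variant_proteins.update(prots)
        as_rows.append(truth)
    as_truth = (
        pd.concat(as_rows, ignore_index=True) if as_rows else pd.DataFrame()
    )

    # Homoeolog pairs: groups in 1:1 copy number across the two subgenomes.
    expression: dict[str, ExpressionMatrix] = {}
    heb_pairs = pd.DataFrame(columns=["pair_id", "gene_a", "gene_b"])
    heb_truth = pd.DataFrame(columns=["pair_id", "tissue", "category"])
    heb_species = ""
    sub_specs = [
        s for s in config.genomes
        if s.genome.ploidy_role == "subgenome_of_allotetraploid"
    ]
    if len(sub_specs) == 2:
        heb_species = sub_specs[0].genome.species
        fam_genes = bundle.genes[bundle.genes["family"] != "none"]
        rows = []
        for grp, sub in fam_genes.groupby("ortholog_group"):
            a = sub[sub["genome"] == sub_specs[0].genome.label]
            b = sub[sub["genome"] == sub_specs[1].genome.label]
            if len(a) == 1 and len(b) == 1:
                rows.append(
                    {"pair_id": grp,
                     "gene_a": a["gene_id"].iloc[0],
                     "gene_b": b["gene_id"].iloc[0]}
                )
        heb_pairs = pd.DataFrame(rows).sort_values("pair_id").reset_index(drop=True)
        matrix, heb_pairs, heb_truth = generate_heb_dataset(
            pairs=heb_pairs,
            tissues=config.tissues,
            p_dom=config.p_dom,
            noise_sd=config.expression_noise_sd,
            n_replicates=config.n_replicates,
            species=heb_species,
            category_weights=config.heb_category_weights,
            rng=np.random.default_rng(np.random.SeedSequence([config.seed, 2])),
        )
        expression[heb_species] = matrix

    # Atlas matrices for the diploid genomes; planted duplicate copies of
    # TRD events stay silent (a pseudogenization signal).
    silent = {
        f"{r.partner}"
        for r in bundle.duplication_truth.itertuples()
        if r.mode == "TRD"
    }
    arng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    for spec in config.genomes:
        if spec.genome.ploidy_role != "diploid":
            continue
        expression[spec.genome.species] = _atlas_matrix(
            bundle.genes, spec.genome.species, config.tissues,
            config.n_replicates, config.expression_noise_sd, arng,
            silent_genes=silent,
        )

    return SyntheticDataset(
        config=config,
        genome_set=bundle,
        transcripts=transcripts,
        variant_proteins=variant_proteins,
        as_truth=as_truth,
        expression=expression,
        heb_pairs=heb_pairs,
        heb_truth=heb_truth,
        heb_species=heb_species,
    )
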