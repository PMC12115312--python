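"""Nine-type taxonomy of splice-variant domain consequences.

Alternative splicing of CPK and CCaMK transcripts can truncate the encoded
protein; relative to the gene's representative architecture the outcome
falls into nine types: a complete kinase domain with progressively fewer
EF-hand motifs (Types 1-4, down to kinase-only), an incomplete kinase
domain (Type 5), or EF-hand motifs alone without the kinase domain
(Types 6-9, from four EF-hands down to one).

Type labels are assigned by the ABSOLUTE domain content of the variant, not
the deficit relative to the reference: a CCaMK (three-EF reference) variant
retaining three EF-hands but no kinase is Type 7, and one with two EF-hands
is Type 8, matching the published CCaMK assignments.  Ca2+-site flags are
reported but ignored for the type label.  Variants that gain domains over
the reference are left unclassified rather than forced into the taxonomy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .core_io import ConfigError, ProteinRecord, TranscriptModel
from .domain_architecture import (
    Architecture,
    ArchitectureClassification,
    build_architecture,
    scan_protein,
)

__all__ = ["AS_TYPES", "ASCall", "classify_as_type", "classify_transcripts"]

AS_TYPES = (
    "CANONICAL", "T1", "T2", "T3", "T4", "T5", "T6", "T7", "T8", "T9",
    "UNCLASSIFIED",
)

#: EF counts keyed to labels for the two kinase states that use counts.
_COMPLETE_KINASE_LABELS = {3: "T1", 2: "T2", 1: "T3", 0: "T4"}
_NO_KINASE_LABELS = {4: "T6", 3: "T7", 2: "T8", 1: "T9"}


@dataclass
class ASCall:
    transcript_id: str
    gene_id: str
    type: str
    variant_arch: Architecture
    reference_arch: Architecture

    def __post_init__(self) -> None:
        if self.type not in AS_TYPES:
            raise ConfigError(f"unknown AS type {self.type!r}")


def classify_as_type(
    variant: Architecture,
    reference: Architecture,
    transcript_id: str = "",
    gene_id: str = "",
) -> ASCall:
    """Classify a variant architecture against a canonical reference.

    The reference must be a CPK/CCaMK canonical layout (complete kinase,
    3-4 EF-hands).  A variant whose signature equals the reference's is
    CANONICAL; otherwise the label follows the variant's absolute content
    (see module docstring).
    """
    if reference.kinase_state != "complete" or not 3 <= reference.ef_count <= 4:
        raise ConfigError(
            "reference architecture must have a complete kinase domain and "
            f"3-4 EF-hands (got {reference.signature!r})"
        )
    if variant.signature == reference.signature:
        label = "CANONICAL"
    elif variant.kinase_state == "incomplete":
        label = "T5"
    elif variant.kinase_state == "complete":
        if variant.ef_count < reference.ef_count:
            label = _COMPLETE_KINASE_LABELS.get(variant.ef_count, "UNCLASSIFIED")
        elif variant.ef_count == reference.ef_count:
            # Same counts but different Ca-site flags: still the canonical
            # domain-count layout for typing purposes.
            label = "CANONICAL"
        else:
            label = "UNCLASSIFIED"
    else:  # kinase absent
        if variant.ef_count <= reference.ef_count:
            label = _NO_KINASE_LABELS.get(variant.ef_count, "UNCLASSIFIED")
        else:
            label = "UNCLASSIFIED"
    return ASCall(
        transcript_id=transcript_id,
        gene_id=gene_id,
        type=label,
        variant_arch=variant,
        reference_arch=reference,
    )


def classify_transcripts(
    transcripts: list[TranscriptModel],
    proteins: dict[str, ProteinRecord],
    references: dict[str, Architecture | ArchitectureClassification],
) -> list[ASCall]:
    """Scan each transcript's protein and classify it against its gene's
    representative architecture.

    ``proteins`` maps transcript_id -> translated protein; ``references``
    maps gene_id -> reference architecture (or a classification whose
    representative is used).  Transcripts without a protein are skipped
    with a warning.
    """
    calls: list[ASCall] = []
    for tx in transcripts:
        prot = proteins.get(tx.transcript_id)
        if prot is None:
            warnings.warn(
                f"transcript {tx.transcript_id} has no protein record; skipped"
            )
            continue
        ref = references[tx.gene_id]
        if isinstance(ref, ArchitectureClassification):
            if ref.representative is None:
                warnings.warn(
                    f"gene {tx.gene_id} has no representative architecture; "
                    f"transcript {tx.transcript_id} skipped"
                )
                continue
            ref = ref.representative
        arch = build_architecture(scan_protein(prot), len(prot))
        calls.append(
            classify_as_type(
                arch, ref, transcript_id=tx.transcript_id, gene_id=tx.gene_id
            )
        )
    return calls
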