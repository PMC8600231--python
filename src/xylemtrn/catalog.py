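"""Gene catalog: per-gene identity, coordinates, functional role and TF family.

The catalog is the annotation backbone of the pipeline.  Roles distinguish the
wood-associated NAC-domain master switches (WND), other transcription factors
(TF), secondary/primary cell wall biosynthetic genes, programmed-cell-death
genes, and unannotated background genes.  Ortholog tags (e.g. "NAC072_class")
mark TFs whose orthology to known regulators drives extra network edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .errors import ValidationError

ROLES = ("WND", "TF", "CW_secondary", "CW_primary", "PCD", "background")
FAMILIES = ("NAC", "MYB", "WRKY", "other", "NA")

#: roles counted as transcription factors for upregulated-TF selection
TF_ROLES = frozenset({"WND", "TF"})
#: roles eligible for the effector (fourth) network layer
EFFECTOR_ROLES = frozenset({"CW_secondary", "CW_primary", "PCD"})

_TSV_HEADER = ["gene_id", "contig", "strand", "tss", "role", "family", "ortholog_tags"]


@dataclass(frozen=True)
class CatalogEntry:
    """One annotated gene."""

    gene_id: str
    contig: str
    strand: str
    tss: int  # 1-based position of the transcription start site
    role: str
    family: str = "NA"
    ortholog_tags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 1:
            raise ValidationError(f"{self.gene_id}: tss must be a positive 1-based coordinate")
        if self.role not in ROLES:
            raise ValidationError(f"{self.gene_id}: unknown role {self.role!r}")
        if self.family not in FAMILIES:
            raise ValidationError(f"{self.gene_id}: unknown family {self.family!r}")
        if self.role == "WND" and self.family != "NAC":
            raise ValidationError(f"{self.gene_id}: WND genes are NAC-family by definition")
        if self.role in EFFECTOR_ROLES and self.family != "NA":
            raise ValidationError(
                f"{self.gene_id}: {self.role} genes carry no TF family (use 'NA')"
            )

    @property
    def is_tf(self) -> bool:
        return self.role in TF_ROLES


class GeneCatalog:
    """Ordered, uniquely-keyed collection of :class:`CatalogEntry`."""

    def __init__(self, entries: Iterable[CatalogEntry]):
        self._entries: list[CatalogEntry] = list(entries)
        self._index: dict[str, CatalogEntry] = {}
        for e in self._entries:
            if e.gene_id in self._index:
                raise ValidationError(f"duplicate gene_id {e.gene_id!r}")
            self._index[e.gene_id] = e

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[CatalogEntry]:
        return iter(self._entries)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def __getitem__(self, gene_id: str) -> CatalogEntry:
        try:
            return self._index[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in catalog") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneCatalog):
            return NotImplemented
        return self._entries == other._entries

    @property
    def gene_ids(self) -> list[str]:
        return [e.gene_id for e in self._entries]

    def with_role(self, *roles: str) -> list[CatalogEntry]:
        for r in roles:
            if r not in ROLES:
                raise ValidationError(f"unknown role {r!r}")
        return [e for e in self._entries if e.role in roles]

    def tf_ids(self) -> set[str]:
        """Gene ids of all transcription factors, master switches included."""
        return {e.gene_id for e in self._entries if e.is_tf}

    # ------------------------------------------------------------------ I/O

    def to_tsv(self, path: str | Path) -> None:
        lines = ["\t".join(_TSV_HEADER)]
        for e in self._entries:
            tags = ";".join(sorted(e.ortholog_tags))
            lines.append(
                "\t".join([e.gene_id, e.contig, e.strand, str(e.tss), e.role, e.family, tags])
            )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneCatalog":
        text = Path(path).read_text().rstrip("\n")
        rows = [line.split("\t") for line in text.split("\n")]
        if not rows or rows[0] != _TSV_HEADER:
            raise ValidationError(f"{path}: missing or malformed catalog header")
        entries = []
        for row in rows[1:]:
            if len(row) != len(_TSV_HEADER):
                raise ValidationError(f"{path}: expected {len(_TSV_HEADER)} columns, got {len(row)}")
            gene_id, contig, strand, tss, role, family, tags = row
            entries.append(
                CatalogEntry(
                    gene_id=gene_id,
                    contig=contig,
                    strand=strand,
                    tss=int(tss),
                    role=role,
                    family=family,
                    ortholog_tags=frozenset(t for t in tags.split(";") if t),
                )
            )
        return cls(entries)
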