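"""Degenerate cis-element scanning of promoter windows.

Consensus notation
------------------
Patterns are written with fixed bases ``A/C/G/T``, the wildcard ``N`` (any
base), and alternative groups ``(A/T)`` or ``[A/T]``.  Example: the 7-bp
secondary wall MYB-responsive element (SMRE) is ``ACC(A/T)A(A/C)(T/C)``; the
programmed-cell-death core element is ``TGTG[T/G/C]``.

Scanning conventions
--------------------
* Coordinates are 0-based, half-open, in promoter-forward orientation (BED
  convention), so minus-strand hits are reported at the position of the
  match on the forward strand.
* All overlapping occurrences are reported.
* An ``N`` in the *subject* sequence never matches any motif position, even
  a motif ``N``; an ``N`` in the *motif* matches any of A/C/G/T.
* Matching is case-insensitive in the subject.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .catalog import CatalogEntry
from .errors import MotifParseError, ValidationError

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASES = "ACGT"
# base -> row index in the per-position allowed table; N (and anything
# unexpected) maps to 4, a row that is never allowed
_ENCODE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DegenerateMotif:
    """Named degenerate consensus: one allowed-nucleotide set per position."""

    name: str
    positions: tuple[frozenset[str], ...]
    source_pattern: str

    def __post_init__(self) -> None:
        if len(self.positions) < 1:
            raise ValidationError(f"motif {self.name!r}: empty consensus")
        for i, pos in enumerate(self.positions):
            if not pos or not pos <= set(_BASES):
                raise ValidationError(
                    f"motif {self.name!r}: position {i} allows {sorted(pos)!r}, "
                    f"expected a nonempty subset of A/C/G/T"
                )

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def variant_count(self) -> int:
        n = 1
        for pos in self.positions:
            n *= len(pos)
        return n

    def reverse_complement(self) -> "DegenerateMotif":
        """Motif matching the reverse complement of this motif's variants."""
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc_positions = tuple(
            frozenset(comp[b] for b in pos) for pos in reversed(self.positions)
        )
        return DegenerateMotif(
            name=self.name,
            positions=rc_positions,
            source_pattern=f"revcomp({self.source_pattern})",
        )


@dataclass(frozen=True, order=True)
class MotifHit:
    """One motif occurrence in a promoter, promoter-forward coordinates."""

    gene_id: str
    start: int  # 0-based
    end: int  # exclusive
    strand: str
    motif_name: str
    matched_seq: str  # forward-strand substring of the promoter


@dataclass
class ElementProfile:
    """Per-gene element presence/absence with raw hit counts."""

    gene_id: str
    hit_counts: dict[str, int]

    def count(self, motif_name: str) -> int:
        return self.hit_counts.get(motif_name, 0)

    def has(self, motif_name: str) -> bool:
        return self.count(motif_name) >= 1

    @property
    def has_snbe(self) -> bool:
        return self.has("SNBE")

    @property
    def has_smre(self) -> bool:
        return self.has("SMRE")

    @property
    def has_wbox(self) -> bool:
        return self.has("WBOX")

    @property
    def has_tgtg(self) -> bool:
        return self.has("TGTG")


def parse_consensus(pattern: str, name: str = "motif") -> DegenerateMotif:
    """Parse a degenerate consensus string into a :class:`DegenerateMotif`.

    Raises :class:`MotifParseError` (with a 1-based column number) on
    unbalanced brackets, empty groups, or illegal characters.
    """
    positions: list[frozenset[str]] = []
    i = 0
    n = len(pattern)
    while i < n:
        ch = pattern[i]
        if ch in _BASES:
            positions.append(frozenset(ch))
            i += 1
        elif ch == "N":
            positions.append(frozenset(_BASES))
            i += 1
        elif ch in "([":
            closer = ")" if ch == "(" else "]"
            j = pattern.find(closer, i + 1)
            if j < 0:
                raise MotifParseError(f"unbalanced {ch!r}", column=i + 1)
            group = pattern[i + 1 : j]
            alts = group.split("/")
            allowed: set[str] = set()
            for alt in alts:
                if len(alt) != 1 or (alt not in _BASES and alt != "N"):
                    raise MotifParseError(
                        f"illegal alternative {alt!r} in group {group!r}", column=i + 1
                    )
                allowed.update(_BASES if alt == "N" else alt)
            if not allowed:
                raise MotifParseError("empty group", column=i + 1)
            positions.append(frozenset(allowed))
            i = j + 1
        elif ch in ")]":
            raise MotifParseError(f"unbalanced {ch!r}", column=i + 1)
        else:
            raise MotifParseError(f"illegal character {ch!r}", column=i + 1)
    if not positions:
        raise MotifParseError("empty pattern", column=1)
    return DegenerateMotif(name=name, positions=tuple(positions), source_pattern=pattern)


def expand_variants(motif: DegenerateMotif, cap: int = 65536) -> list[str]:
    """Complete, sorted, duplicate-free enumeration of a motif's variants.

    Refuses to expand motifs with more than *cap* variants (the 19-bp SNBE
    consensus has millions; enumeration is meant for oracles and planting).
    """
    count = motif.variant_count
    if count > cap:
        raise ValidationError(
            f"motif {motif.name!r} has {count} variants, above the cap of {cap}"
        )
    seqs = {"".join(p) for p in itertools.product(*(sorted(pos) for pos in motif.positions))}
    return sorted(seqs)


def extract_promoter(
    genome: Mapping[str, str], gene: CatalogEntry, window: int = 2000
) -> str:
    """Upstream promoter window of a gene, written 5'->3' toward the gene.

    For a plus-strand gene this is the *window* bases immediately upstream of
    (excluding) the TSS; for a minus-strand gene, the reverse complement of
    the *window* bases immediately downstream of (excluding) the TSS.  The
    window is truncated, never padded, at contig edges; callers should check
    the returned length.
    """
    if window <= 0:
        raise ValidationError(f"window must be positive, got {window}")
    if gene.contig not in genome:
        raise ValidationError(f"{gene.gene_id}: contig {gene.contig!r} not in sequence store")
    contig = genome[gene.contig].upper()
    if not 1 <= gene.tss <= len(contig):
        raise ValidationError(
            f"{gene.gene_id}: tss {gene.tss} outside contig of length {len(contig)}"
        )
    if gene.strand == "+":
        lo = max(0, gene.tss - 1 - window)
        seq = contig[lo : gene.tss - 1]
    else:
        seq = reverse_complement(contig[gene.tss : gene.tss + window])
    if len(seq) < window:
        logger.warning(
            "%s: promoter truncated to %d bp (window %d) at contig edge",
            gene.gene_id, len(seq), window,
        )
    if not seq:
        logger.warning("%s: empty promoter window at contig edge", gene.gene_id)
    return seq


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE_LUT[arr]
    bad = (codes == 4) & ~np.isin(arr, (ord("N"), ord("n")))
    if bad.any():
        pos = int(np.nonzero(bad)[0][0])
        raise ValidationError(f"illegal base {seq[pos]!r} at position {pos}; expected A/C/G/T/N")
    return codes


def _match_starts(codes: np.ndarray, motif: DegenerateMotif) -> np.ndarray:
    """Start offsets where the motif matches the encoded forward strand."""
    L = len(motif)
    n = codes.size
    if n < L:
        return np.empty(0, dtype=np.intp)
    allowed = np.zeros((L, 5), dtype=bool)
    for j, pos in enumerate(motif.positions):
        for b in pos:
            allowed[j, _BASES.index(b)] = True
    ok = allowed[0][codes[: n - L + 1]]
    for j in range(1, L):
        ok &= allowed[j][codes[j : n - L + j + 1]]
    return np.nonzero(ok)[0]


def scan(
    seq: str, motif: DegenerateMotif, gene_id: str = "", strands: str = "both"
) -> list[MotifHit]:
    """All (overlapping) occurrences of *motif* in *seq* on the requested strands.

    Minus-strand hits are matches of the motif on the reverse complement,
    reported in promoter-forward coordinates.  Results are sorted by start,
    then strand ('+' before '-').
    """
    if strands not in ("both", "plus", "minus"):
        raise ValidationError(f"strands must be both|plus|minus, got {strands!r}")
    codes = _encode(seq)
    upper = seq.upper()
    L = len(motif)
    hits: list[MotifHit] = []
    if strands in ("both", "plus"):
        for s in _match_starts(codes, motif):
            hits.append(
                MotifHit(gene_id, int(s), int(s) + L, "+", motif.name, upper[s : s + L])
            )
    if strands in ("both", "minus"):
        # a minus-strand occurrence is a forward-strand match of the
        # reverse-complemented motif at the same forward coordinates
        for s in _match_starts(codes, motif.reverse_complement()):
            hits.append(
                MotifHit(gene_id, int(s), int(s) + L, "-", motif.name, upper[s : s + L])
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_promoters(
    promoters: Mapping[str, str],
    motifs: Mapping[str, DegenerateMotif],
    strands: str = "both",
) -> list[MotifHit]:
    """Scan every promoter with every motif; hits sorted by gene, start, strand."""
    hits: list[MotifHit] = []
    for gene_id in promoters:
        for motif in motifs.values():
            hits.extend(scan(promoters[gene_id], motif, gene_id=gene_id, strands=strands))
    hits.sort(key=lambda h: (h.gene_id, h.start, h.strand, h.motif_name))
    return hits


def element_profiles(
    hits: Iterable[MotifHit],
    motif_names: Sequence[str],
    subset: Iterable[str],
) -> tuple[dict[str, ElementProfile], dict[str, int]]:
    """Per-gene element profiles plus the SNBE/SMRE partition summary.

    *subset* is the gene universe of interest (typically the scanned,
    upregulated TFs).  Hits for genes outside it are ignored with a warning.
    The summary partitions the subset into mutually exclusive, exhaustive
    categories ``snbe_only`` / ``smre_only`` / ``both`` / ``neither`` based
    on SNBE/SMRE presence.
    """
    subset_list = list(dict.fromkeys(subset))
    subset_set = set(subset_list)
    profiles = {
        g: ElementProfile(g, {name: 0 for name in motif_names}) for g in subset_list
    }
    warned: set[str] = set()
    for hit in hits:
        if hit.gene_id not in subset_set:
            if hit.gene_id not in warned:
                logger.warning("hits for %s ignored: gene not in requested subset", hit.gene_id)
                warned.add(hit.gene_id)
            continue
        prof = profiles[hit.gene_id]
        prof.hit_counts[hit.motif_name] = prof.hit_counts.get(hit.motif_name, 0) + 1
    summary = {"snbe_only": 0, "smre_only": 0, "both": 0, "neither": 0}
    for prof in profiles.values():
        if prof.has_snbe and prof.has_smre:
            summary["both"] += 1
        elif prof.has_snbe:
            summary["snbe_only"] += 1
        elif prof.has_smre:
            summary["smre_only"] += 1
        else:
            summary["neither"] += 1
    return profiles, summary


# -------------------------------------------------------------------- I/O


def write_bed(hits: Iterable[MotifHit], path: str | Path) -> None:
    """BED6 export: chrom = gene_id, name = motif name, score = 0."""
    lines = [
        "\t".join([h.gene_id, str(h.start), str(h.end), h.motif_name, "0", h.strand])
        for h in hits
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def load_motif_config(path: str | Path) -> dict[str, DegenerateMotif]:
    """Load a name -> consensus-pattern mapping from a YAML config."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: motif config must map names to patterns")
    return {name: parse_consensus(str(pat), name=name) for name, pat in raw.items()}


def default_motifs() -> dict[str, DegenerateMotif]:
    """The four shipped elements: SNBE, SMRE, WBOX, TGTG.

    SNBE is the 19-bp degenerate secondary wall NAC-binding element consensus
    from the NAC master-switch literature; SMRE is the 7-bp MYB-responsive
    element; WBOX the canonical WRKY-binding element; TGTG the ATAF-class
    core element upstream of programmed-cell-death genes.  All overridable
    via a user config file.
    """
    with resources.as_file(resources.files("xylemtrn.data") / "motifs.yaml") as p:
        return load_motif_config(p)
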