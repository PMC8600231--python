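"""Synthetic data with planted ground truth for the staged-xylem pipeline.

Everything downstream (DE filtering, soft clustering, element scanning,
network construction, concordance classification) is exercised on data
generated here: gene catalogs with realistic role/family composition,
uniform-background promoters with cis-elements planted at known offsets and
strands, and three-stage (three-replicate) expression and protein-abundance
matrices with planted trajectory groups and transcript-protein concordance
labels.  All randomness flows from one explicit integer seed through a
local numpy Generator; identical (config, seed) gives byte-identical files.

Trajectory groups on the log2 scale, relative to the month-1 mean and an
effect size ``e``: group I rises (0, +e, +2e), group II dips and recovers
(0, -e, 0), group III falls (0, -e, -2e), group IV peaks (0, +e, 0), and
``flat`` stays put.  Replicate noise is additive Normal(0, noise_sd) on the
log2 scale; values are exponentiated back to a nonnegative FPKM-like scale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .catalog import CatalogEntry, GeneCatalog
from .errors import PlantingError, ValidationError
from .motifs import DegenerateMotif, default_motifs, reverse_complement, scan

GROUPS = ("I", "II", "III", "IV", "flat")

#: stage-mean offsets (units of effect_size) per trajectory group
_GROUP_SHAPE = {
    "I": (0.0, 1.0, 2.0),
    "II": (0.0, -1.0, 0.0),
    "III": (0.0, -1.0, -2.0),
    "IV": (0.0, 1.0, 0.0),
    "flat": (0.0, 0.0, 0.0),
}

#: sign-flipped counterpart used for discordant proteins
_MIRROR_GROUP = {"I": "III", "III": "I", "II": "IV", "IV": "II", "flat": "I"}

_ROLE_PREFIX = {
    "WND": "WND",
    "TF": "TF",
    "CW_secondary": "CWS",
    "CW_primary": "CWP",
    "PCD": "PCD",
    "background": "BG",
}


@dataclass(frozen=True)
class ExpressionDesign:
    """Shape and noise of the simulated three-stage expression experiment."""

    n_stages: int = 3
    n_reps: int = 3
    base_level: float = 20.0  # FPKM-like month-1 mean
    effect_size: float = 2.0  # log2-scale shift per planted step
    noise_sd: float = 0.3  # log2-scale replicate standard deviation

    def __post_init__(self) -> None:
        if self.n_stages != 3:
            raise ValidationError("trajectory groups are defined for exactly 3 stages")
        if self.n_reps < 2:
            raise ValidationError("need at least 2 replicates per stage")
        if self.base_level <= 0:
            raise ValidationError("base_level must be positive")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be nonnegative")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class PlantedElement:
    gene_id: str
    motif_name: str
    offset: int  # 0-based offset in the promoter window
    strand: str
    variant: str | None = None  # concrete sequence; drawn at random if None


@dataclass
class SyntheticTruth:
    """Machine-readable ground truth emitted alongside generated data."""

    seed: int
    planted_elements: list[PlantedElement] = field(default_factory=list)
    planted_trajectory: dict[str, str] = field(default_factory=dict)
    planted_concordance: dict[str, str] = field(default_factory=dict)

    def merge(self, other: "SyntheticTruth") -> "SyntheticTruth":
        return SyntheticTruth(
            seed=self.seed,
            planted_elements=self.planted_elements + other.planted_elements,
            planted_trajectory={**self.planted_trajectory, **other.planted_trajectory},
            planted_concordance={**self.planted_concordance, **other.planted_concordance},
        )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "seed": self.seed,
            "planted_elements": [
                {
                    "gene_id": e.gene_id,
                    "motif_name": e.motif_name,
                    "offset": e.offset,
                    "strand": e.strand,
                    "variant": e.variant,
                }
                for e in self.planted_elements
            ],
            "planted_trajectory": self.planted_trajectory,
            "planted_concordance": self.planted_concordance,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SyntheticTruth":
        text = Path(source).read_text() if isinstance(source, Path) else source
        payload = json.loads(text)
        return cls(
            seed=payload["seed"],
            planted_elements=[PlantedElement(**e) for e in payload["planted_elements"]],
            planted_trajectory=dict(payload["planted_trajectory"]),
            planted_concordance=dict(payload["planted_concordance"]),
        )


# ---------------------------------------------------------------- catalog


def generate_catalog(
    counts: Mapping[str, int],
    seed: int = 0,
    tf_families: Mapping[str, int] | None = None,
    ortholog_tags: Mapping[str, int] | None = None,
) -> GeneCatalog:
    """Gene catalog with the requested role composition.

    *counts* maps role names (``WND``, ``TF``, ``CW_secondary``/``CW``,
    ``CW_primary``, ``PCD``, ``background``) to gene counts.  *tf_families*
    optionally splits the TF block into leading NAC/MYB/WRKY runs (the rest
    are family ``other``); *ortholog_tags* assigns each tag to that many of
    the first NAC-family TFs.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    normalized: dict[str, int] = {}
    for key, value in counts.items():
        role = "CW_secondary" if key == "CW" else key
        if role not in _ROLE_PREFIX:
            raise ValidationError(f"unknown role {key!r} in counts")
        if value < 0:
            raise ValidationError(f"count for role {key!r} must be >= 0, got {value}")
        normalized[role] = normalized.get(role, 0) + int(value)

    families: list[str] = []
    n_tf = normalized.get("TF", 0)
    if tf_families:
        for fam, n in tf_families.items():
            if fam not in ("NAC", "MYB", "WRKY", "other"):
                raise ValidationError(f"unknown TF family {fam!r}")
            if n < 0:
                raise ValidationError(f"family count for {fam!r} must be >= 0")
            families.extend([fam] * n)
        if len(families) > n_tf:
            raise ValidationError(
                f"tf_families assigns {len(families)} TFs but only {n_tf} requested"
            )
    families.extend(["other"] * (n_tf - len(families)))

    tag_for_nac: dict[int, set[str]] = {}
    if ortholog_tags:
        nac_positions = [i for i, f in enumerate(families) if f == "NAC"]
        cursor = 0
        for tag, n in ortholog_tags.items():
            if cursor + n > len(nac_positions):
                raise ValidationError(
                    f"not enough NAC-family TFs to assign ortholog tag {tag!r}"
                )
            for i in nac_positions[cursor : cursor + n]:
                tag_for_nac.setdefault(i, set()).add(tag)
            cursor += n

    entries: list[CatalogEntry] = []
    gene_index = 0
    for role in _ROLE_PREFIX:
        n = normalized.get(role, 0)
        for i in range(n):
            gene_index += 1
            if role == "WND":
                family = "NAC"
            elif role == "TF":
                family = families[i]
            else:
                family = "NA"
            tags = frozenset(tag_for_nac.get(i, set())) if role == "TF" else frozenset()
            entries.append(
                CatalogEntry(
                    gene_id=f"{_ROLE_PREFIX[role]}{i + 1:04d}",
                    contig="chr1",
                    strand="+" if rng.random() < 0.5 else "-",
                    tss=10_000 * gene_index,
                    role=role,
                    family=family,
                    ortholog_tags=tags,
                )
            )
    return GeneCatalog(entries)


def apply_ortholog_tags(
    catalog: GeneCatalog, tags: Mapping[str, Sequence[str]]
) -> GeneCatalog:
    """New catalog with the given gene_id -> tag list assignments added."""
    for gene_id in tags:
        if gene_id not in catalog:
            raise ValidationError(f"cannot tag unknown gene {gene_id!r}")
    return GeneCatalog(
        replace(e, ortholog_tags=e.ortholog_tags | frozenset(tags.get(e.gene_id, ())))
        for e in catalog
    )


# --------------------------------------------------------------- promoters


def generate_promoters(
    catalog: GeneCatalog,
    motifs: Mapping[str, DegenerateMotif],
    plan: Sequence[PlantedElement],
    window: int = 2000,
    seed: int = 0,
) -> tuple[dict[str, str], SyntheticTruth]:
    """Uniform-background promoters with elements planted at known positions.

    Background is i.i.d. uniform A/C/G/T.  Each plan entry writes one
    concrete variant of its motif at the stated 0-based offset — reverse
    complemented when planted on the minus strand — so scanning recovers it
    at exactly (gene, offset, strand).  Planted elements must not overlap.
    """
    if window <= 0:
        raise ValidationError(f"window must be positive, got {window}")
    occupied: dict[str, list[tuple[int, int]]] = {}
    for el in plan:
        if el.gene_id not in catalog:
            raise PlantingError(f"plan names unknown gene {el.gene_id!r}")
        if el.motif_name not in motifs:
            raise PlantingError(f"{el.gene_id}: unknown motif {el.motif_name!r}")
        if el.strand not in ("+", "-"):
            raise PlantingError(f"{el.gene_id}: strand must be '+' or '-'")
        length = len(motifs[el.motif_name])
        if el.offset < 0 or el.offset + length > window:
            raise PlantingError(
                f"{el.gene_id}: {el.motif_name} at offset {el.offset} does not fit "
                f"in a {window}-bp window"
            )
        span = (el.offset, el.offset + length)
        for other in occupied.get(el.gene_id, []):
            if span[0] < other[1] and other[0] < span[1]:
                raise PlantingError(
                    f"{el.gene_id}: planted elements overlap at {span} and {other}"
                )
        occupied.setdefault(el.gene_id, []).append(span)

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    promoters = {
        e.gene_id: "".join(bases[rng.integers(0, 4, size=window)]) for e in catalog
    }
    truth = SyntheticTruth(seed=seed)
    for el in plan:
        motif = motifs[el.motif_name]
        variant = el.variant
        if variant is None:
            variant = "".join(
                sorted(pos)[rng.integers(0, len(pos))] for pos in motif.positions
            )
        else:
            for b, pos in zip(variant, motif.positions):
                if len(variant) != len(motif) or b not in pos:
                    raise PlantingError(
                        f"{el.gene_id}: {variant!r} is not a variant of {el.motif_name}"
                    )
        written = reverse_complement(variant) if el.strand == "-" else variant
        seq = promoters[el.gene_id]
        promoters[el.gene_id] = (
            seq[: el.offset] + written + seq[el.offset + len(written) :]
        )
        truth.planted_elements.append(replace(el, variant=variant))
    return promoters, truth


def draw_clean_variant(
    motif: DegenerateMotif,
    motifs: Mapping[str, DegenerateMotif],
    rng: np.random.Generator,
    max_tries: int = 1000,
) -> str:
    """A concrete variant of *motif* containing no second motif occurrence.

    Degenerate consensi are permissive enough that a random variant of one
    motif can embed an occurrence of another (e.g. the 19-bp SNBE's wildcard
    core can spell out a TGTG element).  For fixtures whose element
    presence/absence must equal the planted truth exactly, variants are
    rejection-sampled until scanning the bare variant (both strands, all
    motifs) yields only the variant's own forward match.
    """
    for _ in range(max_tries):
        variant = "".join(
            sorted(pos)[rng.integers(0, len(pos))] for pos in motif.positions
        )
        n_hits = sum(len(scan(variant, m)) for m in motifs.values())
        if n_hits == 1:
            return variant
    raise PlantingError(
        f"could not draw a variant of {motif.name!r} free of embedded elements"
    )


def scrub_spurious_hits(
    promoters: Mapping[str, str],
    motifs: Mapping[str, DegenerateMotif],
    truth: SyntheticTruth,
    rng: np.random.Generator,
    max_iter: int = 200,
) -> dict[str, str]:
    """Re-randomize background bases until only planted occurrences remain.

    Uniform 2-kb background contains chance occurrences of every shipped
    element (the analytic rate 2(W-L+1)V/4^L is of order one-to-ten hits per
    gene for SMRE/WBOX/TGTG).  This pass removes them by redrawing the
    offending background bases — never a base inside a planted element —
    until a full scan finds exactly the planted truth.  Used by the
    study-composition fixture; plain :func:`generate_promoters` output keeps
    its chance hits.
    """
    bases = np.array(list("ACGT"))
    planted_keys: dict[str, set[tuple[str, int, str]]] = {}
    spans: dict[str, list[tuple[int, int]]] = {}
    for el in truth.planted_elements:
        planted_keys.setdefault(el.gene_id, set()).add(
            (el.motif_name, el.offset, el.strand)
        )
        spans.setdefault(el.gene_id, []).append(
            (el.offset, el.offset + len(motifs[el.motif_name]))
        )
    cleaned: dict[str, str] = {}
    for gene_id, seq in promoters.items():
        protected = np.zeros(len(seq), dtype=bool)
        for lo, hi in spans.get(gene_id, []):
            protected[lo:hi] = True
        keys = planted_keys.get(gene_id, set())
        for _ in range(max_iter):
            free_positions: set[int] = set()
            n_spurious = 0
            for motif in motifs.values():
                for h in scan(seq, motif, gene_id=gene_id):
                    if (h.motif_name, h.start, h.strand) in keys:
                        continue
                    n_spurious += 1
                    free_positions.update(
                        i for i in range(h.start, h.end) if not protected[i]
                    )
            if n_spurious == 0:
                break
            if not free_positions:
                raise PlantingError(
                    f"{gene_id}: spurious element occurrence lies entirely inside "
                    f"planted elements and cannot be scrubbed"
                )
            arr = np.array(list(seq))
            idx = np.fromiter(sorted(free_positions), dtype=int)
            arr[idx] = bases[rng.integers(0, 4, size=idx.size)]
            seq = "".join(arr)
        else:
            raise PlantingError(f"{gene_id}: could not scrub spurious hits")
        cleaned[gene_id] = seq
    return cleaned


def write_fasta(promoters: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=gene_id, description="") for gene_id, seq in promoters.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# -------------------------------------------------------------- expression


def full_trajectory_plan(
    catalog: GeneCatalog, overrides: Mapping[str, str] | None = None
) -> dict[str, str]:
    """Plan assigning every catalog gene 'flat' except the given overrides."""
    plan = {e.gene_id: "flat" for e in catalog}
    for gene_id, group in (overrides or {}).items():
        if gene_id not in plan:
            raise ValidationError(f"trajectory override names unknown gene {gene_id!r}")
        plan[gene_id] = group
    return plan


def _simulate_matrix(
    ids: Sequence[str],
    groups: Sequence[str],
    design: ExpressionDesign,
    rng: np.random.Generator,
) -> pd.DataFrame:
    base = np.log2(design.base_level)
    shapes = np.asarray(
        [_GROUP_SHAPE[g] for g in groups], dtype=float
    ).reshape(-1, design.n_stages)
    stage_means = base + design.effect_size * shapes
    cols = [
        f"M{s + 1}_r{r + 1}" for s in range(design.n_stages) for r in range(design.n_reps)
    ]
    means = np.repeat(stage_means, design.n_reps, axis=1)
    noise = rng.normal(0.0, design.noise_sd, size=means.shape) if design.noise_sd > 0 else 0.0
    values = np.power(2.0, means + noise)
    return pd.DataFrame(values, index=list(ids), columns=cols).rename_axis("gene_id")


def generate_expression(
    catalog: GeneCatalog,
    design: ExpressionDesign,
    trajectory_plan: Mapping[str, str],
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """FPKM-like matrix (genes x M1_r1..M3_rR) with planted trajectories."""
    for e in catalog:
        if e.gene_id not in trajectory_plan:
            raise ValidationError(f"trajectory plan missing gene {e.gene_id!r}")
    for gene_id, group in trajectory_plan.items():
        if group not in GROUPS:
            raise ValidationError(f"{gene_id}: unknown trajectory group {group!r}")
    if 0 < design.effect_size < 2 * design.noise_sd:
        warnings.warn(
            f"effect_size {design.effect_size} < 2*noise_sd "
            f"{2 * design.noise_sd}: planted trajectories may not be recoverable",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    ids = [e.gene_id for e in catalog]
    matrix = _simulate_matrix(ids, [trajectory_plan[g] for g in ids], design, rng)
    truth = SyntheticTruth(seed=seed, planted_trajectory={g: trajectory_plan[g] for g in ids})
    return matrix, truth


def generate_proteome(
    catalog: GeneCatalog,
    expression_truth: SyntheticTruth,
    concordance_plan: Mapping[str, tuple[str, str]],
    design: ExpressionDesign,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Protein matrix with planted concordance to the transcript trajectories.

    *concordance_plan* maps protein_id -> (gene_id, 'consistent'|'discordant').
    Consistent proteins reuse the transcript's planted trajectory group;
    discordant proteins get the sign-flipped group, so their direction
    differs from the transcript at one or both stage comparisons.
    """
    ids: list[str] = []
    groups: list[str] = []
    truth = SyntheticTruth(seed=seed)
    for protein_id, (gene_id, label) in concordance_plan.items():
        if gene_id not in catalog:
            raise ValidationError(f"{protein_id}: mapped to unknown gene {gene_id!r}")
        if label not in ("consistent", "discordant"):
            raise ValidationError(f"{protein_id}: unknown concordance label {label!r}")
        transcript_group = expression_truth.planted_trajectory.get(gene_id)
        if transcript_group is None:
            raise ValidationError(f"{protein_id}: gene {gene_id!r} has no planted trajectory")
        ids.append(protein_id)
        groups.append(
            transcript_group if label == "consistent" else _MIRROR_GROUP[transcript_group]
        )
        truth.planted_concordance[protein_id] = label
    rng = np.random.default_rng(seed)
    matrix = _simulate_matrix(ids, groups, design, rng)
    matrix.index.name = "protein_id"
    return matrix, truth


# ------------------------------------------------- study-composition bundle


@dataclass
class ReferenceDataset:
    """Complete synthetic dataset mirroring the study's composition."""

    catalog: GeneCatalog
    motifs: dict[str, DegenerateMotif]
    promoters: dict[str, str]
    expression: pd.DataFrame
    proteome: pd.DataFrame
    protein_gene_map: dict[str, str]
    truth: SyntheticTruth
    window: int


def generate_reference_dataset(
    seed: int = 0,
    n_background: int = 200,
    window: int = 2000,
    design: ExpressionDesign | None = None,
) -> ReferenceDataset:
    """Synthetic dataset with the composition of the underlying xylem study.

    Plants: 8 WND master switches; 116 upregulated TFs whose promoters carry
    SNBE only (9), SMRE only (14), or both (93); 98 cell wall genes (90
    secondary, 8 primary; 14 of them without SNBE, 84 with both elements, 30
    carrying an additional W-box); 47 PCD genes, all with SNBE and 40 with
    the TGTG core element; 121 transcript-consistent and 72 discordant
    proteins; plus flat background genes and 10 flat TFs.  Every planted TF,
    WND, CW and PCD gene rises (group I) with a strong effect, and promoter
    backgrounds are purged of chance element occurrences (see
    :func:`scrub_spurious_hits`), so the pipeline's own scanning/selection/
    assignment code recovers the planted composition exactly.
    """
    if design is None:
        design = ExpressionDesign(effect_size=3.0, noise_sd=0.25)
    motifs = default_motifs()
    catalog = generate_catalog(
        counts={
            "WND": 8,
            "TF": 126,
            "CW_secondary": 90,
            "CW_primary": 8,
            "PCD": 47,
            "background": n_background,
        },
        seed=seed,
        tf_families={"NAC": 22, "MYB": 31, "WRKY": 13},
    )

    by_family: dict[str, list[str]] = {"NAC": [], "MYB": [], "WRKY": [], "other": []}
    for e in catalog.with_role("TF"):
        by_family[e.family].append(e.gene_id)
    nac, myb, wrky, other = (by_family[f] for f in ("NAC", "MYB", "WRKY", "other"))

    snbe_only_tfs = nac[:5] + myb[:4]  # 9
    smre_only_tfs = myb[4:13] + other[:5]  # 14
    both_tfs = nac[5:22] + wrky + myb[13:31] + other[5:50]  # 17+13+18+45 = 93
    flat_tfs = other[50:60]  # 10 TFs that stay flat, never selected
    upregulated_tfs = snbe_only_tfs + smre_only_tfs + both_tfs

    # PtoNAC072/PtoNAC045-class orthologs live among the dual-element NAC TFs
    catalog = apply_ortholog_tags(
        catalog,
        {
            both_tfs[0]: ["NAC072_class"],
            both_tfs[1]: ["NAC072_class"],
            both_tfs[2]: ["NAC045_class"],
        },
    )

    cw_ids = [e.gene_id for e in catalog.with_role("CW_secondary", "CW_primary")]
    cw_primary = [e.gene_id for e in catalog.with_role("CW_primary")]
    cw_secondary = [e.gene_id for e in catalog.with_role("CW_secondary")]
    cw_smre_only = cw_primary + cw_secondary[:6]  # the 14 without SNBE
    cw_both = cw_secondary[6:]  # 84 with both elements
    cw_with_wbox = cw_both[:30]
    pcd_ids = [e.gene_id for e in catalog.with_role("PCD")]
    pcd_with_tgtg = pcd_ids[:40]

    def _strand(i: int) -> str:
        return "+" if i % 2 == 0 else "-"

    plan: list[PlantedElement] = []
    for i, g in enumerate(snbe_only_tfs):
        plan.append(PlantedElement(g, "SNBE", 100, _strand(i)))
    for i, g in enumerate(smre_only_tfs):
        plan.append(PlantedElement(g, "SMRE", 300, _strand(i)))
    for i, g in enumerate(both_tfs):
        plan.append(PlantedElement(g, "SNBE", 100, _strand(i)))
        plan.append(PlantedElement(g, "SMRE", 300, _strand(i + 1)))
    for i, g in enumerate(cw_smre_only):
        plan.append(PlantedElement(g, "SMRE", 300, _strand(i)))
    for i, g in enumerate(cw_both):
        plan.append(PlantedElement(g, "SNBE", 100, _strand(i)))
        plan.append(PlantedElement(g, "SMRE", 300, _strand(i + 1)))
    for i, g in enumerate(cw_with_wbox):
        plan.append(PlantedElement(g, "WBOX", 500, _strand(i)))
    for i, g in enumerate(pcd_ids):
        plan.append(PlantedElement(g, "SNBE", 100, _strand(i)))
    for i, g in enumerate(pcd_with_tgtg):
        plan.append(PlantedElement(g, "TGTG", 700, _strand(i)))

    # presence/absence must equal the planted truth exactly: use variants free
    # of embedded elements, then purge chance background occurrences
    aux_rng = np.random.default_rng((seed + 3) % 2**31)
    plan = [
        replace(el, variant=draw_clean_variant(motifs[el.motif_name], motifs, aux_rng))
        for el in plan
    ]
    promoters, promoter_truth = generate_promoters(
        catalog, motifs, plan, window=window, seed=seed
    )
    promoters = scrub_spurious_hits(promoters, motifs, promoter_truth, aux_rng)

    rising = (
        [e.gene_id for e in catalog.with_role("WND")]
        + upregulated_tfs
        + cw_ids
        + pcd_ids
    )
    trajectory_plan = full_trajectory_plan(catalog, {g: "I" for g in rising})
    expression, expr_truth = generate_expression(
        catalog, design, trajectory_plan, seed=seed + 1
    )

    protein_genes = upregulated_tfs + cw_ids[: 193 - len(upregulated_tfs)]
    concordance_plan = {
        f"P_{g}": (g, "consistent" if i < 121 else "discordant")
        for i, g in enumerate(protein_genes)
    }
    proteome, prot_truth = generate_proteome(
        catalog,
        expr_truth,
        concordance_plan,
        design=ExpressionDesign(effect_size=3.0, noise_sd=0.2),
        seed=seed + 2,
    )

    truth = promoter_truth.merge(expr_truth).merge(prot_truth)
    truth.seed = seed
    return ReferenceDataset(
        catalog=catalog,
        motifs=motifs,
        promoters=promoters,
        expression=expression,
        proteome=proteome,
        protein_gene_map={p: g for p, (g, _) in concordance_plan.items()},
        truth=truth,
        window=window,
    )
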