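"""Genome-neighbourhood extraction and pathway classification.

A gene cluster encoding an SQ degradation pathway is recognisable from the
enzyme complement encoded within a window of open reading frames around the
SQase gene: the window here is the seed gene ±k ORFs (default 10) on the same
contig.  Classification is rule-based: each pathway (sulfo-EMP, sulfo-ED,
sulfo-SFT, sulfo-SMO, sulfo-SDO) declares groups of accepted domain tags and
how many groups must be present.  Rules ship as editable YAML
(``data/pathway_rules.yaml``); domain tags are consumed from the feature
table, never computed — running a domain scanner is out of scope.

The classifier also reports whether a classical GH31 SQase and/or a GH188
(NAD+-dependent) SQase gene is present, the signature behind the observation
that many SQ gene clusters carry only the GH188 family member.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

GH31_TAG = "GH31_SQase"
GH188_TAG = "GH188_SQase"

PATHWAY_LABELS = ("sulfo-EMP", "sulfo-ED", "sulfo-SFT", "sulfo-SMO", "sulfo-SDO")


@dataclass(frozen=True)
class GeneFeature:
    """An annotated ORF; coordinates are 1-based inclusive (GenBank style)."""

    genome_id: str
    contig: str
    start: int
    end: int
    strand: str
    locus_id: str
    domain_tags: frozenset[str] = frozenset()
    product: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.locus_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.locus_id}: strand must be + or -")
        object.__setattr__(self, "domain_tags", frozenset(self.domain_tags))


@dataclass(frozen=True)
class Neighborhood:
    """The seed gene plus up to k ORFs each side, in genomic order."""

    genome_id: str
    contig: str
    seed_locus: str
    features: tuple[GeneFeature, ...]
    k: int


@dataclass(frozen=True)
class RuleGroup:
    name: str
    accepted_tags: frozenset[str]
    min_hits: int = 1


@dataclass(frozen=True)
class PathwayRuleSet:
    pathway: str
    required_groups: tuple[RuleGroup, ...]
    min_groups_satisfied: int
    forbidden: frozenset[str] = frozenset()
    cooccurrence_tags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.min_groups_satisfied > len(self.required_groups):
            raise ValueError(
                f"{self.pathway}: min_groups_satisfied exceeds group count"
            )


@dataclass(frozen=True)
class PathwayCall:
    pathway: str  # pathway label, or "unclassified"
    status: str  # "ok" | "unclassified" | "ambiguous"
    matched: dict[str, tuple[str, ...]] = field(default_factory=dict)
    gh31_present: bool = False
    gh188_present: bool = False
    candidates: tuple[str, ...] = ()


def load_rules(path: str | Path | None = None) -> list[PathwayRuleSet]:
    """Load pathway rules from YAML; default rules ship with the package."""
    if path is None:
        src = importlib.resources.files("sqgsuite.data").joinpath(
            "pathway_rules.yaml"
        )
        raw = yaml.safe_load(src.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    rules = []
    for p in raw["pathways"]:
        groups = tuple(
            RuleGroup(
                name=g["name"],
                accepted_tags=frozenset(g["tags"]),
                min_hits=int(g.get("min_hits", 1)),
            )
            for g in p["groups"]
        )
        rules.append(
            PathwayRuleSet(
                pathway=p["pathway"],
                required_groups=groups,
                min_groups_satisfied=int(
                    p.get("min_groups_satisfied", len(groups))
                ),
                forbidden=frozenset(p.get("forbidden", [])),
                cooccurrence_tags=frozenset(p.get("cooccurrence_tags", [])),
            )
        )
    return rules


def extract_neighborhood(
    features: Sequence[GeneFeature], seed_locus: str, k: int = 10
) -> Neighborhood:
    """The seed plus up to k ORFs each side on the seed's contig.

    The window is positional in genomic order, never crosses a contig
    boundary, and is independent of strand.
    """
    by_locus = {f.locus_id: f for f in features}
    if seed_locus not in by_locus:
        raise KeyError(f"seed locus {seed_locus!r} not found")
    seed = by_locus[seed_locus]
    contig_feats = sorted(
        (f for f in features if f.contig == seed.contig),
        key=lambda f: (f.start, f.end, f.locus_id),
    )
    idx = next(
        i for i, f in enumerate(contig_feats) if f.locus_id == seed_locus
    )
    window = contig_feats[max(0, idx - k): idx + k + 1]
    return Neighborhood(
        genome_id=seed.genome_id, contig=seed.contig,
        seed_locus=seed_locus, features=tuple(window), k=k,
    )


def _evaluate(nbhd_tags_per_locus: dict[str, frozenset[str]],
              rules: PathwayRuleSet,
              require_cooccurrence: bool) -> dict[str, tuple[str, ...]] | None:
    all_tags = frozenset().union(*nbhd_tags_per_locus.values()) \
        if nbhd_tags_per_locus else frozenset()
    if rules.forbidden & all_tags:
        return None
    matched: dict[str, tuple[str, ...]] = {}
    for group in rules.required_groups:
        loci = tuple(sorted(
            locus for locus, tags in nbhd_tags_per_locus.items()
            if tags & group.accepted_tags
        ))
        if len(loci) >= group.min_hits:
            matched[group.name] = loci
    if len(matched) < rules.min_groups_satisfied:
        return None
    if require_cooccurrence and rules.cooccurrence_tags:
        if not (rules.cooccurrence_tags & all_tags):
            return None
    return matched


def classify_neighborhood(
    nbhd: Neighborhood,
    rules: Sequence[PathwayRuleSet] | None = None,
    require_cooccurrence: bool = False,
) -> PathwayCall:
    """Evaluate every rule set against the neighbourhood's domain tags.

    Returns the unique satisfied pathway; if several are satisfied, the one
    with the most matched groups wins, and an exact tie is reported with
    status ``ambiguous`` listing all candidates.  GH31/GH188 presence flags
    are set from the tags regardless of the pathway outcome.
    """
    if rules is None:
        rules = load_rules()
    if not rules:
        raise ValueError("rule list must be non-empty")
    tags_per_locus = {f.locus_id: f.domain_tags for f in nbhd.features}
    all_tags = frozenset().union(*tags_per_locus.values()) \
        if tags_per_locus else frozenset()
    gh31 = GH31_TAG in all_tags
    gh188 = GH188_TAG in all_tags

    satisfied: list[tuple[str, dict[str, tuple[str, ...]]]] = []
    for rs in rules:
        matched = _evaluate(tags_per_locus, rs, require_cooccurrence)
        if matched is not None:
            satisfied.append((rs.pathway, matched))
    if not satisfied:
        return PathwayCall("unclassified", "unclassified",
                           gh31_present=gh31, gh188_present=gh188)
    best_n = max(len(m) for _, m in satisfied)
    winners = [(p, m) for p, m in satisfied if len(m) == best_n]
    if len(winners) > 1:
        return PathwayCall(
            "unclassified", "ambiguous",
            gh31_present=gh31, gh188_present=gh188,
            candidates=tuple(sorted(p for p, _ in winners)),
        )
    pathway, matched = winners[0]
    return PathwayCall(pathway, "ok", matched=matched,
                       gh31_present=gh31, gh188_present=gh188)


def cohort_report(
    genomes: Sequence[Sequence[GeneFeature]],
    seeds: Sequence[str],
    rules: Sequence[PathwayRuleSet] | None = None,
    k: int = 10,
    require_cooccurrence: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify a cohort of genomes; per-genome failures become rows, not
    exceptions.

    Returns ``(per_genome, summary)``: one row per genome with pathway and
    SQase-family flags, and counts per pathway × SQase-family combination.
    """
    if len(genomes) != len(seeds):
        raise ValueError("genomes and seeds must have equal length")
    if rules is None:
        rules = load_rules()
    rows = []
    for feats, seed in zip(genomes, seeds):
        genome_id = feats[0].genome_id if feats else ""
        try:
            nbhd = extract_neighborhood(feats, seed, k=k)
            call = classify_neighborhood(
                nbhd, rules, require_cooccurrence=require_cooccurrence
            )
            rows.append({
                "genome_id": genome_id, "seed": seed,
                "pathway": call.pathway, "status": call.status,
                "gh31_present": call.gh31_present,
                "gh188_present": call.gh188_present,
            })
        except Exception as exc:  # noqa: BLE001 — per-genome isolation
            rows.append({
                "genome_id": genome_id, "seed": seed,
                "pathway": "unclassified", "status": f"error: {exc}",
                "gh31_present": False, "gh188_present": False,
            })
    per_genome = pd.DataFrame(
        rows, columns=["genome_id", "seed", "pathway", "status",
                       "gh31_present", "gh188_present"],
    )
    if per_genome.empty:
        summary = pd.DataFrame(
            columns=["pathway", "sqase_family", "n_genomes"]
        )
        return per_genome, summary

    def family(row):
        if row.gh188_present and row.gh31_present:
            return "gh31+gh188"
        if row.gh188_present:
            return "gh188-only"
        if row.gh31_present:
            return "gh31-only"
        return "none"

    per_genome = per_genome.assign(
        sqase_family=[family(r) for r in per_genome.itertuples()]
    )
    summary = (
        per_genome.groupby(["pathway", "sqase_family"], as_index=False)
        .size().rename(columns={"size": "n_genomes"})
    )
    return per_genome, summary


# --- GFF3 and TSV I/O ------------------------------------------------------

def write_gff3(features: Sequence[GeneFeature], path: str | Path) -> None:
    """GFF3 with domain tags in a ``domain=`` attribute (comma-joined)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in sorted(features, key=lambda x: (x.contig, x.start)):
            attrs = [f"ID={f.locus_id}"]
            if f.domain_tags:
                attrs.append("domain=" + ",".join(sorted(f.domain_tags)))
            if f.product:
                attrs.append(f"product={f.product}")
            attrs.append(f"genome_id={f.genome_id}")
            fh.write(
                f"{f.contig}\tsqgsuite\tCDS\t{f.start}\t{f.end}\t.\t"
                f"{f.strand}\t0\t{';'.join(attrs)}\n"
            )


def read_gff3(path: str | Path, genome_id: str | None = None) -> list[GeneFeature]:
    """Parse GFF3 CDS features (via gffutils) into GeneFeatures."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    out = []
    for feat in db.all_features():
        if feat.featuretype not in ("CDS", "gene"):
            continue
        tags = frozenset(
            t for raw in feat.attributes.get("domain", [])
            for t in raw.split(",") if t
        )
        gid = genome_id or feat.attributes.get("genome_id", [""])[0]
        out.append(GeneFeature(
            genome_id=gid, contig=feat.seqid,
            start=feat.start, end=feat.end, strand=feat.strand,
            locus_id=feat.id,
            domain_tags=tags,
            product=feat.attributes.get("product", [""])[0],
        ))
    return out


def features_to_frame(features: Sequence[GeneFeature]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "genome_id": f.genome_id, "contig": f.contig,
            "start": f.start, "end": f.end, "strand": f.strand,
            "locus_id": f.locus_id,
            "domain_tags": ",".join(sorted(f.domain_tags)),
            "product": f.product,
        }
        for f in features
    ])


def frame_to_features(df: pd.DataFrame) -> list[GeneFeature]:
    return [
        GeneFeature(
            genome_id=str(r.genome_id), contig=str(r.contig),
            start=int(r.start), end=int(r.end), strand=str(r.strand),
            locus_id=str(r.locus_id),
            domain_tags=frozenset(
                t for t in str(r.domain_tags).split(",") if t and t != "nan"
            ),
            product="" if pd.isna(r.product) else str(r.product),
        )
        for r in df.itertuples()
    ]
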