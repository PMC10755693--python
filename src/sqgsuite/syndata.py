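"""Synthetic inputs with controlled ground truth for every pipeline stage.

Every generator is deterministic for a fixed seed (bit-identical outputs) and
emulates the statistical structure its consumer assumes:

- ``make_family``: a protein family derived from one random ancestor by
  i.i.d. substitutions, with the per-site substitution probability solved
  from the target mean pairwise identity (stand-in for database retrievals).
- ``make_decoys``: Fisher–Yates shuffles of real-composition sequences — the
  null model for E-value calibration.
- ``make_genome``: a bacterial feature table whose signature genes satisfy
  the corresponding pathway rule set within ±10 ORFs of the seed SQase gene
  (1-based inclusive coordinates, explicit strand, non-overlapping ORFs).
- ``make_kinetic_data``: Michaelis–Menten rates with Gaussian noise.
- ``make_toy_structure``: coordinate sets with analytically known distances,
  rotations and surface areas.

No attempt is made to simulate phylogenies, codon models, operon evolution
or mass-spectrometer noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as bst

from sqgsuite.kinetics import KineticDataset
from sqgsuite.neighborhood import (
    GH31_TAG,
    GH188_TAG,
    GeneFeature,
    PATHWAY_LABELS,
    load_rules,
)
from sqgsuite.records import AMINO_ACIDS, ProteinRecord
from sqgsuite.structgeo import Structure

# --- protein families ------------------------------------------------------


@dataclass(frozen=True)
class FamilySpec:
    """A family of related sequences at a controlled mean pairwise identity."""

    n_members: int
    target_intra_identity: float  # percent, in (0, 100]
    length: int
    seed: int
    prefix: str = "fam"
    taxonomy: str | None = None

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if not 0 < self.target_intra_identity <= 100:
            raise ValueError("target_intra_identity must be in (0, 100]")
        if self.length < 30:
            raise ValueError("length must be >= 30")


def substitution_probability(target_identity_pct: float) -> float:
    """Per-site substitution probability giving the target expected pairwise
    identity between two independently mutated descendants.

    With uniform replacement over the 19 alternatives, two descendants agree
    at a site with probability (1−m)² + m²/19; inverting this quadratic gives
    m.  Identities below the 5% random-descendant floor are infeasible.
    """
    t = target_identity_pct / 100.0
    disc = 1.0 - (20.0 / 19.0) * (1.0 - t)
    if disc < 0:
        raise ValueError(
            f"target identity {target_identity_pct}% is below the ~5% floor "
            "reachable by independent substitution"
        )
    return (1.0 - math.sqrt(disc)) * 19.0 / 20.0


def make_family(spec: FamilySpec) -> list[ProteinRecord]:
    """n_members descendants of one random ancestor; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    ancestor = rng.choice(alphabet, size=spec.length)
    m = substitution_probability(spec.target_intra_identity)
    records = []
    for i in range(spec.n_members):
        seq = ancestor.copy()
        hit = rng.random(spec.length) < m
        if hit.any():
            # uniform replacement over the 19 alternative residues
            offsets = rng.integers(1, 20, size=int(hit.sum()))
            current = np.searchsorted(alphabet, seq[hit])
            seq[hit] = alphabet[(current + offsets) % 20]
        records.append(
            ProteinRecord(
                id=f"{spec.prefix}_{i:03d}",
                seq=seq.tobytes().decode(),
                taxonomy=spec.taxonomy,
            )
        )
    return records


def make_decoys(
    sources: list[ProteinRecord], n: int, seed: int, prefix: str = "decoy"
) -> list[ProteinRecord]:
    """Fisher–Yates shuffles of real-composition sequences: same length and
    composition as their sources, no conserved positional signal."""
    if not sources:
        raise ValueError("need at least one source sequence")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        src = sources[i % len(sources)]
        arr = np.frombuffer(src.seq.encode(), dtype=np.uint8).copy()
        rng.shuffle(arr)
        out.append(ProteinRecord(id=f"{prefix}_{i:03d}",
                                 seq=arr.tobytes().decode()))
    return out


# --- genomes ----------------------------------------------------------------

#: background annotations that never collide with pathway signatures
DECOY_DOMAIN_POOL = (
    "ABC_transporter", "MFS_transporter", "TonB_receptor", "LacI_regulator",
    "GntR_regulator", "histidine_kinase", "response_regulator",
    "acyl_CoA_ligase", "PQQ_dehydrogenase", "sugar_epimerase",
    "peptidase_M23", "radical_SAM", "GGDEF_domain", "cupin_fold",
)


@dataclass(frozen=True)
class GenomeSpec:
    """A synthetic genome with (or without) an SQ degradation gene cluster."""

    pathway_label: str  # one of PATHWAY_LABELS or "none"
    n_background_genes: int = 30
    include_gh31: bool = False
    include_gh188: bool = True
    seed: int = 0
    genome_id: str | None = None

    def __post_init__(self) -> None:
        if self.pathway_label not in PATHWAY_LABELS + ("none",):
            raise ValueError(f"unknown pathway label {self.pathway_label!r}")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be >= 0")


SEED_LOCUS_SUFFIX = "_sqase"


def seed_locus_of(features: list[GeneFeature]) -> str:
    """Locus id of the seed SQase gene in a generated genome."""
    for f in features:
        if f.locus_id.endswith(SEED_LOCUS_SUFFIX):
            return f.locus_id
    raise ValueError("no seed SQase locus in feature list")


def make_genome(spec: GenomeSpec) -> list[GeneFeature]:
    """A non-overlapping 1-based feature table; when a pathway is requested,
    one gene per required signature group is placed within 10 ORFs of the
    seed SQase gene, so the genome satisfies its own rule set."""
    rng = np.random.default_rng(spec.seed)
    gid = spec.genome_id or f"syn_{spec.pathway_label}_{spec.seed}"

    if spec.pathway_label == "none":
        sig_tags: list[str] = []
    else:
        ruleset = next(
            r for r in load_rules() if r.pathway == spec.pathway_label
        )
        sig_tags = [sorted(g.accepted_tags)[0] for g in ruleset.required_groups]

    total = 1 + len(sig_tags) + spec.n_background_genes
    seed_idx = total // 2
    candidates = [
        i for i in range(max(0, seed_idx - 10), min(total, seed_idx + 11))
        if i != seed_idx
    ]
    if len(candidates) < len(sig_tags):
        raise ValueError(
            "genome too small to place all signature genes within ±10 ORFs"
        )
    sig_positions = rng.choice(
        len(candidates), size=len(sig_tags), replace=False
    )
    tag_at = {candidates[p]: t for p, t in zip(sig_positions, sig_tags)}

    seed_tags = set()
    if spec.include_gh188:
        seed_tags.add(GH188_TAG)
    if spec.include_gh31:
        seed_tags.add(GH31_TAG)
    if not seed_tags:
        seed_tags.add("glycoside_hydrolase_like")

    features = []
    pos = 1 + int(rng.integers(0, 500))
    for i in range(total):
        length = int(rng.integers(100, 500)) * 3
        start, end = pos, pos + length - 1
        strand = "+" if rng.random() < 0.5 else "-"
        pos = end + 1 + int(rng.integers(20, 200))
        if i == seed_idx:
            locus = f"{gid}{SEED_LOCUS_SUFFIX}"
            tags = frozenset(seed_tags)
            product = "SQase seed gene"
        elif i in tag_at:
            locus = f"{gid}_g{i:04d}"
            tags = frozenset({tag_at[i]})
            product = tag_at[i].replace("_", " ")
        else:
            locus = f"{gid}_g{i:04d}"
            tags = frozenset({
                DECOY_DOMAIN_POOL[int(rng.integers(len(DECOY_DOMAIN_POOL)))]
            })
            product = "hypothetical protein"
        features.append(GeneFeature(
            genome_id=gid, contig=f"{gid}_contig1",
            start=start, end=end, strand=strand,
            locus_id=locus, domain_tags=tags, product=product,
        ))
    return features


# --- kinetics ---------------------------------------------------------------

def make_kinetic_data(
    vmax: float, km: float, e0: float | None,
    s_values, noise_sd: float = 0.0, seed: int = 0,
    substrate_label: str = "",
) -> KineticDataset:
    """Rates v = Vmax·S/(KM+S) + ε, ε ~ N(0, noise_sd²); noise_sd=0 gives the
    exact curve.  Works identically for cofactor-activation grids."""
    if vmax <= 0 or km <= 0:
        raise ValueError("vmax and km must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    s = np.asarray(s_values, dtype=float)
    if np.any(s <= 0):
        raise ValueError("all concentrations must be > 0")
    v = vmax * s / (km + s)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd, size=s.shape)
    return KineticDataset(s, v, e0=e0, substrate_label=substrate_label)


# --- toy structures ---------------------------------------------------------

def _atom_array(records) -> bst.AtomArray:
    """records: (chain, res_id, res_name, atom_name, element, xyz)."""
    n = len(records)
    arr = bst.AtomArray(n)
    for i, (chain, res_id, res_name, atom_name, element, xyz) in enumerate(records):
        arr.chain_id[i] = chain
        arr.res_id[i] = res_id
        arr.res_name[i] = res_name
        arr.atom_name[i] = atom_name
        arr.element[i] = element
        arr.coord[i] = xyz
    arr.hetero[:] = False
    return arr


def _rotation_about_z(deg: float) -> np.ndarray:
    t = math.radians(deg)
    return np.array([
        [math.cos(t), -math.sin(t), 0.0],
        [math.sin(t), math.cos(t), 0.0],
        [0.0, 0.0, 1.0],
    ])


def make_toy_structure(kind: str, **params):
    """Coordinate fixtures with analytically known geometry.

    - ``sphere-pair``: two carbon atoms at ``separation`` Å (default 3.4)
      along z — exact pairwise distance.
    - ``helix-dimer``: two CA-only ideal helices (chains A and B) offset by
      ``offset`` Å along x — an interface with a buriable contact surface.
    - ``rotated-copy``: one residue (N, CA, CB, CG) and a copy whose CG is
      rotated by ``angle`` degrees about the Cα–Cβ bond — exact χ1
      difference.  Returns ``(original, rotated)``.
    """
    if kind == "sphere-pair":
        d = float(params.get("separation", 3.4))
        arr = _atom_array([
            ("A", 1, "LIG", "C1", "C", (0.0, 0.0, 0.0)),
            ("A", 2, "LIG", "C1", "C", (0.0, 0.0, d)),
        ])
        return Structure(arr, name="sphere-pair")

    if kind == "helix-dimer":
        n_res = int(params.get("n_res", 20))
        offset = float(params.get("offset", 6.0))
        radius, rise, twist = 2.3, 1.5, math.radians(100.0)
        rows = []
        for chain, dx in (("A", 0.0), ("B", offset)):
            for i in range(n_res):
                xyz = (radius * math.cos(i * twist) + dx,
                       radius * math.sin(i * twist),
                       rise * i)
                rows.append((chain, i + 1, "ALA", "CA", "C", xyz))
        return Structure(_atom_array(rows), name="helix-dimer")

    if kind == "rotated-copy":
        angle = float(params.get("angle", 72.0))
        # CA at origin, CB on +z: the Cα–Cβ axis is the z axis, so rotating
        # CG about z changes chi1 by exactly `angle`
        base = [
            ("A", 1, "TYR", "N", "N", (1.45, 0.0, -0.52)),
            ("A", 1, "TYR", "CA", "C", (0.0, 0.0, 0.0)),
            ("A", 1, "TYR", "CB", "C", (0.0, 0.0, 1.53)),
            ("A", 1, "TYR", "CG", "C", (1.25, 0.0, 2.19)),
        ]
        rot = _rotation_about_z(angle)
        rotated = [
            (c, r, rn, an, el, tuple(rot @ np.asarray(xyz)) if an == "CG" else xyz)
            for c, r, rn, an, el, xyz in base
        ]
        return (Structure(_atom_array(base), name="chi1-ref"),
                Structure(_atom_array(rotated), name="chi1-rot"))

    raise ValueError(f"unknown toy-structure kind {kind!r}")
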