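"""Seeded synthetic inputs with the structure every pipeline stage assumes.

The generator plants the statistical features the real corpora carry —
compound clusters with high within-cluster substructure similarity,
superclass labels aligned with clusters, side-effect profiles coupled to
chemical structure, within-cluster enzyme sharing, and species-abundance
tables of tunable evenness — and emits the ground truth alongside, so
downstream tests have oracles. Fingerprints are statistical stand-ins
with the right similarity geometry, not valid molecules.

One global seed expands into fixed per-stage child seeds (a counter-based
spawn), so adding a stage never perturbs earlier stages' draws and the
same spec + seed reproduces byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dominance import EnzymeTaxonAbundance, ecsd
from .fingerprints import FP_NBITS, Compound, Fingerprint, write_compounds
from .toxicity import SideEffectProfile

_STAGES = {
    "compounds": 1,
    "side_effects": 2,
    "enzymes": 3,
    "abundance": 4,
    "descriptors": 5,
    "uses": 6,
}


@dataclass(frozen=True)
class FixtureSpec:
    """Planted-structure parameters for one synthetic dataset.

    Defaults keep fixtures small (200 compounds, 30 concepts, 10
    enzymes, 20 species) while leaving the planted cluster signal easily
    detectable: cluster templates set ~20% of the 881 bits, so
    within-cluster Tanimoto sits near 0.9 and between-cluster near 0.1.
    """

    n_compounds: int = 200
    n_clusters: int = 4
    shared_bit_fraction: float = 0.2
    bit_flip_noise: float = 0.02
    category_proportions: tuple[tuple[str, float], ...] = (
        ("drug", 0.3),
        ("food", 0.5),
        ("endogenous", 0.2),
    )
    superclass_alignment: float = 0.9
    vocabulary_size: int = 30
    concepts_per_drug: int = 6
    baseline_prevalence: float = 0.05
    coupling: float = 0.7
    n_enzymes: int = 10
    enzyme_sharing: float = 0.7
    background_enzyme_rate: float = 0.02
    n_species: int = 20
    evenness: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "shared_bit_fraction",
            "bit_flip_noise",
            "superclass_alignment",
            "baseline_prevalence",
            "coupling",
            "enzyme_sharing",
            "background_enzyme_rate",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {value}")
        for name in (
            "n_compounds",
            "n_clusters",
            "vocabulary_size",
            "concepts_per_drug",
            "n_enzymes",
            "n_species",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_clusters > self.n_compounds:
            raise ValueError("n_clusters may not exceed n_compounds")
        total = sum(p for _, p in self.category_proportions)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError("category proportions must sum to 1")


def _rng(spec: FixtureSpec, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(_STAGES[stage],))
    )


def generate_compounds(
    spec: FixtureSpec,
) -> tuple[list[Compound], dict[str, int]]:
    """Fingerprinted compounds with planted clusters; returns the
    compounds and the true compound -> cluster mapping."""
    rng = _rng(spec, "compounds")
    n_template_bits = max(1, round(spec.shared_bit_fraction * FP_NBITS))
    templates = [
        rng.choice(FP_NBITS, size=n_template_bits, replace=False)
        for _ in range(spec.n_clusters)
    ]
    cats, probs = zip(*spec.category_proportions)
    compounds: list[Compound] = []
    clusters: dict[str, int] = {}
    width = len(str(spec.n_compounds - 1))
    for i in range(spec.n_compounds):
        cluster = i % spec.n_clusters
        bits = np.zeros(FP_NBITS, dtype=bool)
        bits[templates[cluster]] = True
        flips = rng.random(FP_NBITS) < spec.bit_flip_noise
        bits ^= flips
        category = str(rng.choice(cats, p=probs))
        if rng.random() < spec.superclass_alignment:
            superclass = f"SC{cluster}"
        else:
            superclass = f"SC{rng.integers(spec.n_clusters)}"
        cid = f"C{i:0{width}d}"
        compounds.append(
            Compound(
                compound_id=cid,
                name=f"compound-{i}",
                category=category,
                superclass=superclass,
                fingerprint=Fingerprint(bits),
            )
        )
        clusters[cid] = cluster
    return compounds, clusters


def generate_side_effects(
    spec: FixtureSpec,
    compounds: Sequence[Compound],
    clusters: Mapping[str, int],
) -> list[SideEffectProfile]:
    """Side-effect profiles for drug compounds, coupled to structure.

    Each cluster owns a pool of concepts; every concept draw comes from
    the drug's cluster pool with probability ``coupling`` and from the
    whole vocabulary otherwise, plus a ``baseline_prevalence`` chance of
    each background concept. Coupling 0 therefore severs the structure–
    toxicity relationship; coupling 1 makes cluster mates nearly
    toxicity-identical.
    """
    if spec.vocabulary_size < spec.concepts_per_drug:
        raise ValueError("vocabulary smaller than the per-drug concept draw")
    rng = _rng(spec, "side_effects")
    vocab = [f"SE{j:03d}" for j in range(spec.vocabulary_size)]
    pools = [
        [vocab[j] for j in range(spec.vocabulary_size) if j % spec.n_clusters == c]
        for c in range(spec.n_clusters)
    ]
    profiles = []
    for comp in compounds:
        if comp.category != "drug":
            continue
        pool = pools[clusters[comp.compound_id]]
        concepts: set[str] = set()
        for _ in range(spec.concepts_per_drug):
            source = pool if rng.random() < spec.coupling else vocab
            concepts.add(str(source[rng.integers(len(source))]))
        for concept in vocab:
            if rng.random() < spec.baseline_prevalence:
                concepts.add(concept)
        profiles.append(
            SideEffectProfile(
                compound_id=comp.compound_id, concepts=frozenset(concepts)
            )
        )
    return profiles


def generate_enzyme_map(
    spec: FixtureSpec,
    compounds: Sequence[Compound],
    clusters: Mapping[str, int],
) -> set[tuple[str, str]]:
    """EC–compound associations with within-cluster sharing.

    Enzymes are assigned round-robin to clusters; each compound carries
    each of its cluster's enzymes with probability ``enzyme_sharing``
    (so a within-cluster pair shares a given enzyme with probability
    sharing²) and any other enzyme at the rare
    ``background_enzyme_rate``.
    """
    rng = _rng(spec, "enzymes")
    ecs = [f"3.2.1.{j + 1}" for j in range(spec.n_enzymes)]
    owner = {ec: j % spec.n_clusters for j, ec in enumerate(ecs)}
    out: set[tuple[str, str]] = set()
    for comp in compounds:
        cluster = clusters[comp.compound_id]
        for ec in ecs:
            if owner[ec] == cluster:
                if rng.random() < spec.enzyme_sharing:
                    out.add((ec, comp.compound_id))
            elif rng.random() < spec.background_enzyme_rate:
                out.add((ec, comp.compound_id))
    return out


def generate_descriptors(
    spec: FixtureSpec,
    compounds: Sequence[Compound],
    clusters: Mapping[str, int],
) -> pd.DataFrame:
    """Cluster-correlated physiochemical descriptors, two per family
    (geometry, functional groups, aromaticity, amino acid composition,
    polarity, hydrophobicity)."""
    from .enzyme_model import DESCRIPTOR_GROUPS

    rng = _rng(spec, "descriptors")
    names = [f"{g}_{k}" for g in DESCRIPTOR_GROUPS for k in (1, 2)]
    centers = rng.normal(0.0, 2.0, size=(spec.n_clusters, len(names)))
    rows = {}
    for comp in compounds:
        c = clusters[comp.compound_id]
        rows[comp.compound_id] = centers[c] + rng.normal(0.0, 1.0, len(names))
    df = pd.DataFrame.from_dict(rows, orient="index", columns=names)
    df.index.name = "compound_id"
    return df


def generate_uses(
    spec: FixtureSpec, compounds: Sequence[Compound]
) -> dict[str, list[str]]:
    """One therapeutic-use label per drug compound, from a small pool."""
    rng = _rng(spec, "uses")
    pool = [f"use-{j}" for j in range(8)]
    return {
        comp.compound_id: [str(pool[rng.integers(len(pool))])]
        for comp in compounds
        if comp.category == "drug"
    }


def _solve_target_counts(target: float, k: int, total: int) -> dict[str, int]:
    # one dominant species at fraction x, the rest even: in the large-N
    # limit D(x) = x^2 + (1-x)^2/(k-1), monotone on x in [1/k, 1]
    d_target = 1.0 - target
    if k == 1 or target == 0.0:
        return {"S000": total}
    a = 1.0 + 1.0 / (k - 1)
    b = -2.0 / (k - 1)
    c = 1.0 / (k - 1) - d_target
    x = (-b + math.sqrt(b * b - 4 * a * c)) / (2 * a)
    n1 = round(x * total)
    rest = total - n1
    base, extra = divmod(rest, k - 1)
    counts = {"S000": n1}
    for j in range(1, k):
        counts[f"S{j:03d}"] = base + (1 if j <= extra else 0)
    return {sp: n for sp, n in counts.items() if n > 0}


def generate_abundance(
    spec: FixtureSpec, target_ecsd: float | None = None
) -> list[EnzymeTaxonAbundance]:
    """Species-abundance tables per enzyme.

    Without a target, per-enzyme counts are a Dirichlet draw whose
    concentration is the ``evenness`` parameter, scaled to 2000
    individuals (evenness → ∞ approaches equal abundance, hence ECs_D →
    1 − 1/k). With ``target_ecsd`` a single table is solved (one
    dominant species, remainder even, N = 10⁴) so the realised score is
    within 0.02 of the target; targets outside [0, 1 − 1/k] are
    unreachable and error.
    """
    k = spec.n_species
    if target_ecsd is not None:
        if not 0.0 <= target_ecsd <= 1.0 - 1.0 / k:
            raise ValueError(
                f"target_ecsd {target_ecsd} unreachable with {k} species "
                f"(must be in [0, {1.0 - 1.0 / k:.4f}])"
            )
        table = EnzymeTaxonAbundance(
            enzyme_id="3.2.1.1",
            counts=_solve_target_counts(target_ecsd, k, total=10_000),
        )
        achieved = ecsd(table).ecsd
        assert abs(achieved - target_ecsd) <= 0.02, (achieved, target_ecsd)
        return [table]
    rng = _rng(spec, "abundance")
    tables = []
    for j in range(spec.n_enzymes):
        shares = rng.dirichlet(np.full(k, spec.evenness))
        counts = np.round(shares * 2000).astype(int)
        if counts.sum() < 2:  # degenerate draw; force scoreability
            counts[:2] += 1
        tables.append(
            EnzymeTaxonAbundance(
                enzyme_id=f"3.2.1.{j + 1}",
                counts={
                    f"S{s:03d}": int(n)
                    for s, n in enumerate(counts)
                    if n > 0
                },
            )
        )
    return tables


def write_fixture(spec: FixtureSpec, outdir) -> dict[str, Path]:
    """Write the full five-table fixture plus descriptors and the
    planted-truth sidecar; returns the path of each artifact."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    compounds, clusters = generate_compounds(spec)
    profiles = generate_side_effects(spec, compounds, clusters)
    enzyme_map = generate_enzyme_map(spec, compounds, clusters)
    descriptors = generate_descriptors(spec, compounds, clusters)
    uses = generate_uses(spec, compounds)
    abundance = generate_abundance(spec)

    paths = {name: outdir / f"{name}.tsv" for name in (
        "compounds", "side_effects", "enzyme_map", "abundance",
        "uses", "descriptors",
    )}
    write_compounds(compounds, paths["compounds"])
    pd.DataFrame(
        [
            {"compound_id": p.compound_id, "concept_id": c, "concept_name": c}
            for p in profiles
            for c in sorted(p.concepts)
        ]
    ).to_csv(paths["side_effects"], sep="\t", index=False)
    pd.DataFrame(
        sorted(enzyme_map), columns=["ec_number", "compound_id"]
    ).to_csv(paths["enzyme_map"], sep="\t", index=False)
    pd.DataFrame(
        [
            {"ec_number": t.enzyme_id, "species_id": sp, "count": n}
            for t in abundance
            for sp, n in sorted(t.counts.items())
        ]
    ).to_csv(paths["abundance"], sep="\t", index=False)
    pd.DataFrame(
        [
            {"compound_id": cid, "use_label": label}
            for cid, labels in sorted(uses.items())
            for label in labels
        ]
    ).to_csv(paths["uses"], sep="\t", index=False)
    descriptors.reset_index().to_csv(paths["descriptors"], sep="\t", index=False)

    truth = {
        "spec": asdict(spec),
        "clusters": clusters,
        "coupling": spec.coupling,
        "enzyme_sharing": spec.enzyme_sharing,
    }
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True))
    paths["truth"] = truth_path
    return paths


def read_uses(path) -> dict[str, list[str]]:
    """Read a drug-use TSV: ``compound_id use_label``."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.compound_id, []).append(row.use_label)
    return out
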