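"""Probability that a compound pair shares a metabolising enzyme.

Compound pairs are labelled ``associated`` when both members are known
substrates of at least one common EC number, ``non-associated``
otherwise. A margin-based classifier (RBF support-vector machine with
Platt-style probability calibration) is trained on symmetric pair
features — the Tanimoto substructure similarity plus the absolute
difference of each physiochemical descriptor — and the fitted
probability of association is summarised as a curve over substructure-
similarity bins. On data where association is coupled to substructure
overlap the curve rises monotonically: structurally alike compounds are
more likely to be substrates of the same enzyme.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .fingerprints import Compound, canonical_pair, tanimoto

logger = logging.getLogger(__name__)

LABEL_ASSOCIATED = "associated"
LABEL_NON_ASSOCIATED = "non-associated"

#: Descriptor families the physiochemical table is expected to draw from.
DESCRIPTOR_GROUPS = (
    "geometry",
    "functional_groups",
    "aromaticity",
    "amino_acid_composition",
    "polarity",
    "hydrophobicity",
)


def read_enzyme_map(path) -> set[tuple[str, str]]:
    """Read an enzyme map TSV (``ec_number compound_id``) to unique pairs."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"ec_number", "compound_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"enzyme map missing columns: {sorted(missing)}")
    return set(zip(df["ec_number"], df["compound_id"]))


def resolve_enzyme_map(
    associations: set[tuple[str, str]], known_ids: set[str]
) -> set[tuple[str, str]]:
    """Drop map rows whose compound id is not in the compound table."""
    resolved = {(ec, cid) for ec, cid in associations if cid in known_ids}
    skipped = len(associations) - len(resolved)
    if skipped:
        logger.warning("skipped %d enzyme-map rows with unknown compounds", skipped)
    return resolved


def compound_ec_sets(
    associations: set[tuple[str, str]]
) -> dict[str, frozenset[str]]:
    out: dict[str, set[str]] = {}
    for ec, cid in associations:
        out.setdefault(cid, set()).add(ec)
    return {cid: frozenset(ecs) for cid, ecs in out.items()}


def read_descriptors(path) -> pd.DataFrame:
    """Read a descriptor TSV: ``compound_id`` + one numeric column per
    descriptor; returns a frame indexed by compound id."""
    df = pd.read_csv(path, sep="\t", dtype={"compound_id": str})
    if "compound_id" not in df.columns:
        raise ValueError("descriptor table missing compound_id column")
    df = df.set_index("compound_id")
    values = df.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("descriptor table contains non-finite values")
    return df


def label_pairs(
    compounds: Sequence[Compound],
    enzyme_map: set[tuple[str, str]],
    descriptors: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Label every unordered compound pair by shared-enzyme membership.

    Features per pair: ``tanimoto`` plus ``d_<name>`` absolute
    differences for each descriptor column (order-invariant by
    construction). Association means a non-empty intersection of the
    two compounds' EC sets.
    """
    if not enzyme_map:
        raise ValueError("enzyme map must be non-empty")
    ids = {c.compound_id for c in compounds}
    ec_sets = compound_ec_sets(resolve_enzyme_map(enzyme_map, ids))
    empty: frozenset[str] = frozenset()
    desc_cols: list[str] = []
    desc_values: dict[str, np.ndarray] = {}
    if descriptors is not None:
        desc_cols = list(descriptors.columns)
        desc_values = {
            cid: descriptors.loc[cid].to_numpy(dtype=float)
            for cid in descriptors.index
            if cid in ids
        }
    rows = []
    for i, a in enumerate(compounds):
        for b in compounds[i + 1 :]:
            pair = canonical_pair(a.compound_id, b.compound_id)
            shared = ec_sets.get(a.compound_id, empty) & ec_sets.get(
                b.compound_id, empty
            )
            row = {
                "compound_a": pair[0],
                "compound_b": pair[1],
                "tanimoto": tanimoto(a.fingerprint, b.fingerprint),
                "label": LABEL_ASSOCIATED if shared else LABEL_NON_ASSOCIATED,
            }
            if desc_cols:
                da = desc_values.get(a.compound_id)
                db = desc_values.get(b.compound_id)
                if da is None or db is None:
                    continue
                diffs = np.abs(da - db)
                row.update(
                    {f"d_{col}": diffs[k] for k, col in enumerate(desc_cols)}
                )
            rows.append(row)
    return pd.DataFrame(rows)


def feature_columns(examples: pd.DataFrame) -> list[str]:
    return ["tanimoto"] + sorted(
        c for c in examples.columns if c.startswith("d_")
    )


def _median_heuristic_gamma(x: np.ndarray, rng: np.random.Generator) -> float:
    """RBF bandwidth from the median pairwise squared distance on a
    subsample of the (already standardised) training features."""
    idx = rng.choice(len(x), size=min(len(x), 500), replace=False)
    sub = x[idx]
    sq = np.sum((sub[:, None, :] - sub[None, :, :]) ** 2, axis=-1)
    med = float(np.median(sq[np.triu_indices_from(sq, k=1)]))
    if med <= 0:
        return 1.0 / max(x.shape[1], 1)
    return 1.0 / (2.0 * med)


@dataclass
class PairAssociationModel:
    """Standardiser + RBF SVM with Platt-calibrated probabilities."""

    scaler: StandardScaler
    clf: CalibratedClassifierCV
    feature_names: list[str]

    def predict_proba(self, examples: pd.DataFrame) -> np.ndarray:
        """P(associated) per row; the complement is P(non-associated)."""
        x = self.scaler.transform(
            examples[self.feature_names].to_numpy(dtype=float)
        )
        proba = self.clf.predict_proba(x)
        assoc_col = list(self.clf.classes_).index(LABEL_ASSOCIATED)
        return proba[:, assoc_col]

    def predict(self, examples: pd.DataFrame) -> np.ndarray:
        probs = self.predict_proba(examples)
        return np.where(probs >= 0.5, LABEL_ASSOCIATED, LABEL_NON_ASSOCIATED)


def train_probability_model(
    examples: pd.DataFrame,
    seed: int = 0,
    max_imbalance: float = 5.0,
) -> PairAssociationModel:
    """Fit the calibrated pair classifier on labelled examples.

    The majority class is down-sampled to at most ``max_imbalance``:1
    before fitting (shared-enzyme labels are heavily skewed toward
    non-association on real corpora). Standardisation is fit on the
    training examples only, so applying the model to shifted test
    features involves no leakage.
    """
    labels = examples["label"].to_numpy()
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("training data must contain both labels")
    rng = np.random.default_rng(seed)
    counts = {c: int((labels == c).sum()) for c in classes}
    minority = min(counts, key=counts.get)
    majority = max(counts, key=counts.get)
    keep = np.ones(len(examples), dtype=bool)
    cap = int(max_imbalance * counts[minority])
    if counts[majority] > cap:
        maj_idx = np.flatnonzero(labels == majority)
        drop = rng.choice(
            maj_idx, size=counts[majority] - cap, replace=False
        )
        keep[drop] = False
    train = examples.loc[keep]
    cols = feature_columns(examples)
    x = train[cols].to_numpy(dtype=float)
    y = train["label"].to_numpy()
    scaler = StandardScaler().fit(x)
    xs = scaler.transform(x)
    gamma = _median_heuristic_gamma(xs, rng)
    # sigmoid (Platt) calibration on unshuffled stratified folds keeps the
    # fit deterministic given the seed-fixed down-sampling above
    n_cal = min(5, min(int((y == c).sum()) for c in classes))
    clf = CalibratedClassifierCV(
        SVC(kernel="rbf", gamma=gamma),
        method="sigmoid",
        cv=max(n_cal, 2),
        ensemble=False,
    )
    clf.fit(xs, y)
    return PairAssociationModel(scaler=scaler, clf=clf, feature_names=cols)


def cross_validated_probabilities(
    examples: pd.DataFrame, seed: int = 0, n_splits: int = 5
) -> np.ndarray:
    """Out-of-fold P(associated) from stratified K-fold retraining.

    Each fold's model (scaler included) is fit on the other folds only,
    so every probability is a held-out prediction.
    """
    labels = examples["label"].to_numpy()
    probs = np.full(len(examples), np.nan)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    for k, (train_idx, test_idx) in enumerate(
        skf.split(np.zeros(len(examples)), labels)
    ):
        model = train_probability_model(
            examples.iloc[train_idx], seed=seed + k
        )
        probs[test_idx] = model.predict_proba(examples.iloc[test_idx])
    return probs


def probability_vs_similarity_curve(
    examples: pd.DataFrame,
    probabilities: np.ndarray,
    bins: int = 10,
) -> pd.DataFrame:
    """Mean predicted association probability per similarity bin and class.

    Bin edges are uniform on [0, 1]; the top bin is closed so a
    similarity of exactly 1 is counted. Empty bins are reported with
    count 0 and NaN mean.
    """
    if bins < 1:
        raise ValueError("bins must be positive")
    edges = np.linspace(0.0, 1.0, bins + 1)
    sim = examples["tanimoto"].to_numpy(dtype=float)
    labels = examples["label"].to_numpy()
    idx = np.clip(np.digitize(sim, edges[1:-1]), 0, bins - 1)
    rows = []
    for b in range(bins):
        for cls in (LABEL_ASSOCIATED, LABEL_NON_ASSOCIATED):
            mask = (idx == b) & (labels == cls)
            n = int(mask.sum())
            rows.append(
                {
                    "bin_low": edges[b],
                    "bin_high": edges[b + 1],
                    "class": cls,
                    "n": n,
                    "mean_probability": (
                        float(probabilities[mask].mean()) if n else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)


def write_curve(curve: pd.DataFrame, path) -> None:
    """Curve TSV: ``bin_low bin_high class n mean_probability``."""
    curve.to_csv(path, sep="\t", index=False)
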