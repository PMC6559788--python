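"""Compounds, 881-bit substructure fingerprints and Tanimoto similarity.

Each compound carries a PubChem-style binary substructure key vector of
fixed dimension 881, in which every bit flags the presence of a discrete
chemical feature (an element count, ring system, functional group, ...).
Pairwise chemical similarity is the Tanimoto coefficient over the set
bits, which rewards shared substructures and ignores shared absences.

Fingerprints travel in the CACTVS wire format used by PubChem: a base64
string whose decoded bytes are a 4-byte big-endian bit-length prefix
followed by the MSB-first bit-packed vector, zero-padded to a byte
boundary.
"""

from __future__ import annotations

import base64
import binascii
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Fixed dimension of the PubChem substructure key vector.
FP_NBITS = 881

#: Number of payload bytes holding 881 bits (last 7 bits are padding).
_FP_NBYTES = (FP_NBITS + 7) // 8

CATEGORIES = frozenset({"drug", "food", "endogenous", "other"})


class FingerprintFormatError(ValueError):
    """Malformed CACTVS payload (bad base64, truncation, nonzero padding)."""


class FingerprintDimensionError(ValueError):
    """Fingerprint is not 881 bits, or two fingerprints disagree in length."""


@dataclass(frozen=True)
class Fingerprint:
    """An 881-bit binary substructure key vector."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.bits, dtype=bool)
        if arr.ndim != 1 or arr.size != FP_NBITS:
            raise FingerprintDimensionError(
                f"fingerprint must have exactly {FP_NBITS} bits, got {arr.size}"
            )
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "bits", arr)

    @property
    def popcount(self) -> int:
        """Number of set bits."""
        return int(self.bits.sum())

    @classmethod
    def from_indices(cls, indices: Iterable[int]) -> "Fingerprint":
        """Build a fingerprint from the positions of its set bits."""
        bits = np.zeros(FP_NBITS, dtype=bool)
        idx = np.fromiter(indices, dtype=np.int64)
        if idx.size and (idx.min() < 0 or idx.max() >= FP_NBITS):
            raise FingerprintDimensionError(
                f"bit index out of range 0..{FP_NBITS - 1}"
            )
        bits[idx] = True
        return cls(bits)

    def to_indices(self) -> np.ndarray:
        """Positions of the set bits, ascending."""
        return np.flatnonzero(self.bits)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Fingerprint):
            return NotImplemented
        return bool(np.array_equal(self.bits, other.bits))

    def __hash__(self) -> int:
        return hash(self.bits.tobytes())


@dataclass(frozen=True)
class Compound:
    """A food, drug or endogenous small molecule with its fingerprint.

    ``compound_id`` is an opaque unique identifier (a PubChem CID when the
    inputs are real); ``superclass`` is the second level of the ClassyFire
    chemical taxonomy when annotated, else ``None``.
    """

    compound_id: str
    name: str
    category: str
    fingerprint: Fingerprint
    superclass: str | None = None

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValueError("compound_id must be non-empty")
        if self.category not in CATEGORIES:
            raise ValueError(
                f"category {self.category!r} not in {sorted(CATEGORIES)}"
            )


def decode_cactvs(encoded: str) -> Fingerprint:
    """Decode a base64 CACTVS fingerprint string to an 881-bit vector.

    The decoded byte stream must carry a 4-byte big-endian bit-length
    prefix (which must declare 881) followed by the MSB-first bit-packed
    vector with zero pad bits.
    """
    try:
        raw = base64.b64decode(encoded, validate=True)
    except (binascii.Error, ValueError) as exc:
        raise FingerprintFormatError(f"invalid base64: {exc}") from exc
    if len(raw) < 4:
        raise FingerprintFormatError("payload shorter than 4-byte length prefix")
    declared = int.from_bytes(raw[:4], "big")
    if declared != FP_NBITS:
        raise FingerprintDimensionError(
            f"declared bit length {declared} != {FP_NBITS}"
        )
    data = raw[4:]
    if len(data) != _FP_NBYTES:
        raise FingerprintFormatError(
            f"expected {_FP_NBYTES} payload bytes for {FP_NBITS} bits, "
            f"got {len(data)}"
        )
    unpacked = np.unpackbits(np.frombuffer(data, dtype=np.uint8))
    if unpacked[FP_NBITS:].any():
        raise FingerprintFormatError("nonzero padding bits")
    return Fingerprint(unpacked[:FP_NBITS].astype(bool))


def encode_cactvs(fp: Fingerprint) -> str:
    """Encode a fingerprint to its base64 CACTVS string (decode inverse)."""
    packed = np.packbits(fp.bits.astype(np.uint8))
    raw = FP_NBITS.to_bytes(4, "big") + packed.tobytes()
    return base64.b64encode(raw).decode("ascii")


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| over set bits.

    Defined as 0.0 when both fingerprints are all-zero (the 0/0 case):
    featureless records should not look identical to each other.
    """
    inter = int(np.count_nonzero(a.bits & b.bits))
    union = int(np.count_nonzero(a.bits | b.bits))
    if union == 0:
        return 0.0
    return inter / union


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Order a compound-id pair canonically (lexicographic min first)."""
    if a == b:
        raise ValueError(f"pair endpoints must differ, got {a!r} twice")
    return (a, b) if a < b else (b, a)


def pairwise_similarity(
    compounds: Sequence[Compound],
) -> dict[tuple[str, str], float]:
    """All-pairs Tanimoto table keyed by canonical ordered id pair.

    Vectorised: intersection counts come from one boolean matrix product,
    so the table scales to thousands of compounds.
    """
    if len(compounds) < 2:
        raise ValueError("need at least 2 compounds")
    ids = [c.compound_id for c in compounds]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate compound ids")
    mat = np.stack([c.fingerprint.bits for c in compounds]).astype(np.int32)
    pop = mat.sum(axis=1)
    inter = mat @ mat.T
    union = pop[:, None] + pop[None, :] - inter
    out: dict[tuple[str, str], float] = {}
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            u = union[i, j]
            score = float(inter[i, j] / u) if u else 0.0
            out[canonical_pair(ids[i], ids[j])] = score
    return out


def read_compounds(path) -> list[Compound]:
    """Read a compound TSV: ``compound_id name category superclass fingerprint``.

    The fingerprint column is auto-detected as either a base64 CACTVS
    string or a comma-separated list of set-bit indices. Rows with a
    missing fingerprint are dropped with a logged warning; real inputs
    are incomplete and should not abort the build.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"compound_id", "name", "category", "superclass", "fingerprint"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"compound table missing columns: {sorted(missing)}")
    compounds: list[Compound] = []
    dropped = 0
    for row in df.itertuples(index=False):
        raw = row.fingerprint.strip()
        if not raw:
            dropped += 1
            continue
        fp = _parse_fingerprint_field(raw)
        compounds.append(
            Compound(
                compound_id=row.compound_id,
                name=row.name,
                category=row.category,
                superclass=row.superclass or None,
                fingerprint=fp,
            )
        )
    if dropped:
        logger.warning(
            "dropped %d compound rows lacking a fingerprint", dropped
        )
    ids = [c.compound_id for c in compounds]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate compound ids in table")
    return compounds


def _parse_fingerprint_field(raw: str) -> Fingerprint:
    # comma-separated integers vs base64: an index list contains only
    # digits and commas, which is never valid base64 for a 115-byte payload
    stripped = raw.replace(",", "")
    if stripped.isdigit():
        return Fingerprint.from_indices(
            int(tok) for tok in raw.split(",") if tok
        )
    return decode_cactvs(raw)


def write_compounds(compounds: Sequence[Compound], path) -> None:
    """Write the compound TSV dialect consumed by :func:`read_compounds`."""
    rows = [
        {
            "compound_id": c.compound_id,
            "name": c.name,
            "category": c.category,
            "superclass": c.superclass or "",
            "fingerprint": encode_cactvs(c.fingerprint),
        }
        for c in compounds
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
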