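"""Optional online adapter: fetch real CACTVS fingerprints from PubChem.

The core pipeline consumes precomputed fingerprints from file; this
adapter exists for small interactive lookups (a handful of CIDs) via
the PUG-REST ``Fingerprint2D`` property, which returns the base64
CACTVS payload that :func:`gutchem.fingerprints.decode_cactvs` expects.
It requires network access and is not used by any offline code path.
"""

from __future__ import annotations

import json
import urllib.request

from .fingerprints import Fingerprint, decode_cactvs

PUG_REST = "https://pubchem.ncbi.nlm.nih.gov/rest/pug"

#: CIDs of a few reference steroids handy for sanity checks.
KNOWN_CIDS = {
    "digoxin": 2724385,
    "cortisone": 222786,
    "progesterone": 5994,
}


def fetch_fingerprint(cid: int, timeout: float = 10.0) -> Fingerprint:
    """Fetch and decode the 881-bit fingerprint of one PubChem CID."""
    url = f"{PUG_REST}/compound/cid/{int(cid)}/property/Fingerprint2D/JSON"
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        payload = json.load(resp)
    props = payload["PropertyTable"]["Properties"][0]
    return decode_cactvs(props["Fingerprint2D"])


def fetch_fingerprints(
    cids: dict[str, int], timeout: float = 10.0
) -> dict[str, Fingerprint]:
    """Fetch several CIDs, keyed by the caller's names."""
    return {
        name: fetch_fingerprint(cid, timeout=timeout)
        for name, cid in cids.items()
    }
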