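"""Download PDB entries for worked examples.

Only the examples and the 1UBY worked-example test use this; the core
library never touches the network.
"""

from __future__ import annotations

import os
import urllib.request

__all__ = ["fetch_pdb"]

RCSB_URL = "https://files.rcsb.org/download/{pdb_id}.pdb"


def fetch_pdb(pdb_id: str, cache_dir: str = "scratch/pdb",
              timeout: float = 15.0) -> str:
    """Return PDB-format text for ``pdb_id``, caching under ``cache_dir``.

    Raises ``OSError`` when the entry is not cached and the network is
    unreachable.
    """
    pdb_id = pdb_id.upper()
    path = os.path.join(cache_dir, f"{pdb_id}.pdb")
    if os.path.exists(path):
        with open(path) as fh:
            return fh.read()
    url = RCSB_URL.format(pdb_id=pdb_id)
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        text = resp.read().decode()
    os.makedirs(cache_dir, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(text)
    return text
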