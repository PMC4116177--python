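"""Download the PDB entries listed in a structure manifest.

Helper for the real-structure pocket reproduction; requires network access
and is deliberately separate from the tested analysis core.

Usage:
    python scripts/fetch_structures.py examples/real_structures [manifest.yaml]
"""

from __future__ import annotations

import sys
import urllib.request
from pathlib import Path

import yaml

RCSB = "https://files.rcsb.org/download/{pdb_id}.pdb"


def main(argv: list[str]) -> int:
    if not argv:
        print(__doc__, file=sys.stderr)
        return 1
    target = Path(argv[0])
    manifest_path = Path(argv[1]) if len(argv) > 1 else target / "manifest.yaml"
    manifest = yaml.safe_load(manifest_path.read_text())
    target.mkdir(parents=True, exist_ok=True)
    for entry in manifest["structures"]:
        pdb_id = entry.get("id") or Path(entry["path"]).stem
        dest = target / entry["path"]
        if dest.exists():
            print(f"{pdb_id}: already present")
            continue
        url = RCSB.format(pdb_id=pdb_id.upper())
        print(f"{pdb_id}: fetching {url}")
        with urllib.request.urlopen(url, timeout=60) as resp:
            dest.write_bytes(resp.read())
    return 0


if __name__ == "__main__":
    raise SystemExit(main(sys.argv[1:]))
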