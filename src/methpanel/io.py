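"""Plain-TSV I/O with ``#`` metadata headers.

Every table written by the pipeline is tab-separated with a header row and
leading ``# key: value`` comment lines carrying tool version, seed and config
hash, so runs are diffable and reproducible from their on-disk outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__

#: sentinel written for missing values (undetermined Ct, n.a. frequencies)
NA_REP = "NA"


def read_tsv(path: str | Path, **kwargs: Any) -> pd.DataFrame:
    """Read a methpanel TSV, skipping ``#`` comment lines."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    # round_trip parsing so written floats re-read bit-identically
    kwargs.setdefault("float_precision", "round_trip")
    return pd.read_csv(path, sep="\t", comment="#", na_values=[NA_REP], **kwargs)


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    meta: Mapping[str, Any] | None = None,
) -> Path:
    """Write *df* as TSV with a ``# key: value`` metadata preamble."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# methpanel: {__version__}"]
    for key, value in (meta or {}).items():
        lines.append(f"# {key}: {value}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, sep="\t", index=False, na_rep=NA_REP)
    return path


def read_tsv_meta(path: str | Path) -> dict[str, str]:
    """Return the ``# key: value`` preamble of a methpanel TSV as a dict."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    return meta


def config_hash(obj: Any) -> str:
    """Stable short hash of a JSON-serialisable config object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
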