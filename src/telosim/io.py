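"""Config, cohort CSV, and run-manifest input/output.

Cohort CSV schema (wide, one row per individual, header mandatory,
UTF-8, '.' decimal separator)::

    id, exposed, true_baseline_kb, true_change_kb, true_followup_kb,
    proxy_baseline, proxy_followup

The two proxy columns may be absent (truth-only cohort).  Floats are
serialized with 17 significant digits so a write/read round trip is
bit-stable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
from pydantic import ValidationError

from .cohort import Cohort
from .params import CohortParams

TRUTH_COLUMNS = ["id", "exposed", "true_baseline_kb", "true_change_kb", "true_followup_kb"]
PROXY_COLUMNS = ["proxy_baseline", "proxy_followup"]


def load_config(path) -> CohortParams:
    """Load and validate cohort parameters from a JSON or YAML mapping.

    Field names mirror :class:`CohortParams` exactly; omitted fields
    take the package defaults, unknown keys and out-of-range values are
    rejected with the offending field named.  An empty file yields the
    full default parameter set.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text) if text.strip() else {}
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping of parameter names to values")
    try:
        return CohortParams(**raw)
    except ValidationError as err:
        details = "; ".join(
            f"{'.'.join(str(x) for x in e['loc']) or '<root>'}: {e['msg']}"
            for e in err.errors()
        )
        raise ValueError(f"invalid config {path}: {details}") from err


def write_cohort_csv(cohort: Cohort, path) -> None:
    """Write a cohort to the wide CSV schema (full float precision)."""
    cohort.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_cohort_csv(path) -> Cohort:
    """Read a cohort from the wide CSV schema.

    Missing proxy columns give a truth-only cohort.  Generative params
    are unknown for user-supplied files, so ``params`` is ``None`` and
    operations that need the generating distribution will refuse.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path} is empty; expected a cohort CSV with a header")
    missing = [c for c in TRUTH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path} is missing required columns: {missing}")
    if len(df) == 0:
        raise ValueError(f"{path} has a header but no individuals")

    numeric = TRUTH_COLUMNS[2:] + [c for c in PROXY_COLUMNS if c in df.columns]
    for col in numeric:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int((parsed.isna() | df[col].isna()).idxmax())
            raise ValueError(f"{path}: non-numeric or missing value in column {col!r}, row {row}")
        df[col] = parsed.astype(float)

    has_proxy = all(c in df.columns for c in PROXY_COLUMNS)
    return Cohort(
        ids=df["id"].to_numpy(),
        exposed=df["exposed"].astype(bool).to_numpy(),
        true_baseline_kb=df["true_baseline_kb"].to_numpy(),
        true_change_kb=df["true_change_kb"].to_numpy(),
        true_followup_kb=df["true_followup_kb"].to_numpy(),
        proxy_baseline=df["proxy_baseline"].to_numpy() if has_proxy else None,
        proxy_followup=df["proxy_followup"].to_numpy() if has_proxy else None,
    )


@dataclass(frozen=True)
class RunManifest:
    """Provenance record written next to every CLI output file."""

    command: str
    parameters: Dict
    seed: Optional[int]
    version: str
    timestamp: str
    output_digests: Dict[str, str]

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def sha256_file(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(command: str, parameters: Dict, seed: Optional[int], outputs) -> Path:
    """Digest the outputs and write ``<first output>.manifest.json``."""
    from . import __version__

    outputs = [Path(p) for p in outputs]
    manifest = RunManifest(
        command=command,
        parameters=_jsonable(parameters),
        seed=seed,
        version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
        output_digests={p.name: sha256_file(p) for p in outputs},
    )
    path = outputs[0].with_suffix(outputs[0].suffix + ".manifest.json")
    manifest.write(path)
    return path


def _jsonable(obj):
    if isinstance(obj, CohortParams):
        return obj.model_dump()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
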