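"""Report files for scan results: TSV table, JSON geometry, provenance log."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import Ellipsoid
from .inference import ScanResult, select_reported

logger = logging.getLogger("peakclust")

TABLE_COLUMNS = ["N", "M", "x", "y", "z", "volume_mm3", "major_radius_mm",
                 "mean_value", "p_corrected"]


def ellipsoid_to_dict(e: Ellipsoid) -> dict:
    return {
        "center_mm": e.center_mm.tolist(),
        "axes": e.axes.tolist(),
        "radii_mm": e.radii_mm.tolist(),
        "major_radius_mm": e.major_radius_mm,
        "volume_mm3": e.volume_mm3,
        "n_participants": e.n_participants,
        "members": {str(pid): {"location_mm": p.location_mm.tolist(),
                               "value": None if np.isnan(p.value) else float(p.value),
                               "rank": int(p.rank)}
                    for pid, p in e.members.items()},
    }


def report(scan: ScanResult, out_dir: str | Path, seed: int | None = None,
           settings: dict | None = None) -> dict[str, Path]:
    """Write the scan's TSV table, full JSON geometry, and a provenance log.

    The TSV mirrors the reporting table layout (N, M, centre coordinates,
    volume, major radius, mean value, corrected p); the JSON additionally
    carries the full ellipsoid geometry per row and the engine settings.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = scan.to_frame()
    tsv_path = out / "scan_result.tsv"
    if len(df):
        table = df[df["significant"]][TABLE_COLUMNS + ["p_raw"]]
    else:
        table = pd.DataFrame(columns=TABLE_COLUMNS + ["p_raw"])
    table.to_csv(tsv_path, sep="\t", index=False, float_format="%.4g")

    payload = {
        "m_range": list(scan.m_range),
        "alpha_family": scan.alpha_family,
        "threshold": scan.threshold,
        "seed": seed,
        "settings": settings or {},
        "reported": [
            {"M": r.m, "N": r.n_participants, "p_raw": r.p_raw,
             "p_corrected": r.p_corrected,
             "ellipsoid": ellipsoid_to_dict(r.ellipsoid)}
            for r in select_reported(scan)
        ],
        "rows": [
            {"M": r.m, "N": r.n_participants, "p_raw": r.p_raw,
             "p_corrected": r.p_corrected, "significant": r.significant,
             "ellipsoid": ellipsoid_to_dict(r.ellipsoid)}
            for r in scan.rows
        ],
    }
    json_path = out / "scan_result.json"
    json_path.write_text(json.dumps(payload, indent=1))

    log_path = out / "run_log.txt"
    lines = [f"seed: {seed}", f"m_range: {scan.m_range}",
             f"alpha_family: {scan.alpha_family}",
             f"corrected threshold: {scan.threshold:.6g}"]
    for k, v in (settings or {}).items():
        lines.append(f"{k}: {v}")
    log_path.write_text("\n".join(lines) + "\n")
    logger.info("report written to %s", out)
    return {"tsv": tsv_path, "json": json_path, "log": log_path}
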