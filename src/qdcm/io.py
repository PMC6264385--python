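"""File formats, manifests and provenance for the command-line pipeline.

All volumes are NIfTI-1; traces and designs are delimited text; the
manifest is YAML.  Haemoglobin is accepted in the customary g/dl and
normalised to g/ml internally (guarded by range checks).  Written maps
carry the affine of the reference image and a JSON provenance record
(configuration hash, package version, seeds, lookup-table hash).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "Manifest",
    "read_manifest",
    "load_volume",
    "write_maps",
    "config_hash",
]


def config_hash(config: dict) -> str:
    """Stable hash of a configuration dictionary."""
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


@dataclass(frozen=True)
class Manifest:
    """Validated description of one dataset's inputs."""

    te1: Path
    te2: Path
    m0: Path
    mask: Path
    trace: Path  # three-column time/petco2/peto2 text (or CO2 two-column)
    hb: float  # g/ml after normalisation
    out_dir: Path
    trace_o2: Path | None = None  # optional separate O2 two-column file
    tag_first: bool = True
    acquisition: dict = field(default_factory=dict)

    def as_config(self) -> dict:
        d = {k: str(v) for k, v in self.__dict__.items()}
        d["acquisition"] = dict(self.acquisition)
        return d


def _normalise_hb(hb: float) -> float:
    """Accept g/dl (customary, ~14) or g/ml (~0.14)."""
    if 5.0 < hb < 25.0:
        return hb / 100.0
    if 0.05 < hb < 0.25:
        return float(hb)
    raise ValueError(f"hb={hb} not interpretable as g/dl or g/ml")


def read_manifest(path) -> Manifest:
    """Load and validate a YAML manifest; paths resolve relative to it."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("manifest must be a YAML mapping")
    base = path.parent
    required = ("te1", "te2", "m0", "mask", "trace", "hb")
    for key in required:
        if key not in raw:
            raise ValueError(f"manifest missing required key '{key}'")
    paths = {}
    for key in ("te1", "te2", "m0", "mask", "trace", "trace_o2"):
        if raw.get(key) is None:
            continue
        p = (base / raw[key]).resolve()
        if not p.exists():
            raise ValueError(f"manifest key '{key}': file not found: {p}")
        paths[key] = p
    out_dir = (base / raw.get("out", "qdcm_out")).resolve()
    return Manifest(
        te1=paths["te1"], te2=paths["te2"], m0=paths["m0"],
        mask=paths["mask"], trace=paths["trace"],
        trace_o2=paths.get("trace_o2"),
        hb=_normalise_hb(float(raw["hb"])),
        out_dir=out_dir,
        tag_first=bool(raw.get("tag_first", True)),
        acquisition=dict(raw.get("acquisition", {})),
    )


def load_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Return (data, affine) of a NIfTI image as float64."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), img.affine


def write_maps(
    maps: dict[str, np.ndarray],
    affine: np.ndarray,
    out_dir,
    provenance: dict | None = None,
) -> list[Path]:
    """Write parameter maps as NIfTI plus a JSON provenance record.

    Idempotent: re-running with identical inputs rewrites identical
    files.  Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, data in maps.items():
        p = out_dir / f"{name}.nii.gz"
        nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine).to_filename(
            str(p))
        written.append(p)
    prov = dict(provenance or {})
    prov.setdefault("maps", sorted(maps))
    prov["config_hash"] = config_hash(prov)
    p = out_dir / "provenance.json"
    with open(p, "w") as fh:
        json.dump(prov, fh, indent=2, sort_keys=True, default=str)
    written.append(p)
    return written
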