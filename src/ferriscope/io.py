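"""Reading and writing the on-disk formats of the measurement pipeline.

Image stacks travel either as NPZ (array ``echoes`` shaped
``[n_echo, ny, nx]``) or as NIfTI (one volume per echo), each with a JSON
sidecar ``{"echo_times_ms": [...], "noise_sd": float|null}``.  ROI masks
are same-shape boolean arrays (NPZ) or run-length encodings in JSON.
Contours are JSON ``[x, y]`` point lists per slice.  Fit results serialize
to JSON records mirroring the fit dataclass fields.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ferriscope.cardiac_mapping import MyocardialContours
from ferriscope.synthetic_data import Phantom

__all__ = [
    "load_stack",
    "save_stack_npz",
    "load_mask",
    "rle_encode_mask",
    "rle_decode_mask",
    "load_contours",
    "save_contours",
    "save_phantom",
]


def _read_sidecar(path: Path) -> dict:
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing JSON sidecar for {path}")
    return json.loads(sidecar.read_text())


def load_stack(path: str | Path) -> tuple[np.ndarray, np.ndarray, float | None]:
    """Load a multi-echo stack -> (stack [n_echo, ny, nx], echo_times_ms, noise_sd).

    ``.npz`` files must hold an ``echoes`` array; ``.nii``/``.nii.gz`` files
    one volume per echo along the last axis.  Echo times come from the JSON
    sidecar next to the file.
    """
    path = Path(path)
    if path.suffix == ".npz":
        meta = _read_sidecar(path)
        stack = np.load(path)["echoes"]
    elif path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        base = path.name[: -len(".nii.gz")] if path.name.endswith(".nii.gz") else path.stem
        meta = _read_sidecar(path.parent / base)
        vol = np.asarray(nib.load(str(path)).dataobj, dtype=float)
        stack = np.moveaxis(vol, -1, 0)
    else:
        raise ValueError(f"unsupported stack format: {path}")
    te = np.asarray(meta["echo_times_ms"], dtype=float)
    if stack.shape[0] != te.size:
        raise ValueError("echo count in stack does not match sidecar echo_times_ms")
    return stack, te, meta.get("noise_sd")


def save_stack_npz(path: str | Path, stack: np.ndarray, echo_times_ms,
                   noise_sd: float | None = None) -> None:
    path = Path(path)
    np.savez_compressed(path, echoes=np.asarray(stack))
    sidecar = {"echo_times_ms": [float(t) for t in echo_times_ms],
               "noise_sd": None if noise_sd in (None, 0) else float(noise_sd)}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def rle_encode_mask(mask: np.ndarray) -> dict:
    """Run-length encode a boolean mask (row-major runs of True pixels)."""
    flat = np.asarray(mask, dtype=bool).ravel()
    edges = np.flatnonzero(np.diff(np.concatenate([[False], flat, [False]])))
    starts, ends = edges[::2], edges[1::2]
    return {"shape": list(mask.shape),
            "runs": [[int(s), int(e - s)] for s, e in zip(starts, ends)]}


def rle_decode_mask(rle: dict) -> np.ndarray:
    flat = np.zeros(int(np.prod(rle["shape"])), dtype=bool)
    for start, length in rle["runs"]:
        flat[start:start + length] = True
    return flat.reshape(rle["shape"])


def load_mask(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".npz":
        return np.load(path)["mask"].astype(bool)
    if path.suffix == ".json":
        return rle_decode_mask(json.loads(path.read_text()))
    raise ValueError(f"unsupported mask format: {path}")


def save_contours(path: str | Path, contours: dict[str, MyocardialContours]) -> None:
    """Write per-slice contours as JSON [x, y] point lists."""
    payload = {
        level: {
            "slice_level": c.slice_level,
            "endocardium": c.endocardium.tolist(),
            "epicardium": c.epicardium.tolist(),
            "reference_angle": c.reference_angle,
        }
        for level, c in contours.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_contours(path: str | Path) -> dict[str, MyocardialContours]:
    payload = json.loads(Path(path).read_text())
    return {
        level: MyocardialContours(
            slice_level=d["slice_level"],
            endocardium=d["endocardium"],
            epicardium=d["epicardium"],
            reference_angle=d.get("reference_angle", 90.0),
        )
        for level, d in payload.items()
    }


def save_phantom(phantom: Phantom, out_dir: str | Path) -> dict:
    """Serialize a phantom: one NPZ stack per slice, masks, truth metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"geometry": phantom.spec.geometry, "slices": []}
    for s in phantom.slices:
        stem = out / f"stack_{s.name}"
        save_stack_npz(stem.with_suffix(".npz"), s.stack, phantom.echo_times_ms,
                       phantom.noise_sigma or None)
        masks = {f"region_{k}": m for k, m in enumerate(s.region_masks)}
        np.savez_compressed(out / f"masks_{s.name}.npz", **masks)
        manifest["slices"].append({"name": s.name,
                                   "stack": stem.with_suffix(".npz").name,
                                   "masks": f"masks_{s.name}.npz",
                                   "truth_t2star_ms": list(s.truth_t2star)})
    if phantom.slices[0].contours is not None:
        save_contours(out / "contours.json",
                      {s.name: s.contours for s in phantom.slices})
        manifest["contours"] = "contours.json"
    (out / "phantom.json").write_text(json.dumps(manifest, indent=1))
    return manifest
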