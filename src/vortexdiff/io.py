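"""Serialization: HDF5 for fields and datasets, PNG/TIFF intensity export,
npz checkpoints with an architecture-hash sidecar."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import tifffile
from PIL import Image

from .digits import DatasetManifest
from .nn.network import LGDiffNet, NetworkConfig
from .optics import ComplexField
from .pipeline import SceneConfig, SimulatedDataset

__all__ = [
    "save_field", "load_field", "export_intensity_png", "export_intensity_tiff",
    "save_dataset", "load_dataset", "save_checkpoint", "load_checkpoint",
]


def save_field(path, field: ComplexField) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("field", data=field.values)
        d.attrs["pitch"] = field.pitch
        d.attrs["wavelength"] = field.wavelength
        d.attrs["z_position"] = field.z_position


def load_field(path) -> ComplexField:
    with h5py.File(path, "r") as f:
        d = f["field"]
        return ComplexField(d[...], float(d.attrs["pitch"]), float(d.attrs["wavelength"]),
                            float(d.attrs["z_position"]))


def _norm8(intensity: np.ndarray) -> np.ndarray:
    lo, hi = float(intensity.min()), float(intensity.max())
    if hi == lo:
        return np.zeros(intensity.shape, dtype=np.uint8)
    return np.round(255.0 * (intensity - lo) / (hi - lo)).astype(np.uint8)


def export_intensity_png(path, intensity: np.ndarray) -> None:
    """8-bit PNG of a (min-max scaled) intensity image."""
    Image.fromarray(_norm8(intensity), mode="L").save(path)


def export_intensity_tiff(path, intensity: np.ndarray) -> None:
    """16-bit TIFF of a (min-max scaled) intensity image."""
    lo, hi = float(intensity.min()), float(intensity.max())
    scaled = np.zeros(intensity.shape) if hi == lo else (intensity - lo) / (hi - lo)
    tifffile.imwrite(path, np.round(65535.0 * scaled).astype(np.uint16))


def save_dataset(path, ds: SimulatedDataset) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("stacks", data=ds.stacks, compression="gzip")
        f.create_dataset("truths", data=ds.truths, compression="gzip")
        f.create_dataset("classes", data=ds.classes)
        f.create_dataset("rotations", data=ds.rotations)
        for split in ("train", "val", "test"):
            f.create_dataset(f"split/{split}", data=getattr(ds.manifest, f"{split}_ids"))
        f.attrs["arm"] = ds.arm
        f.attrs["corpus_hash"] = ds.corpus_hash
        f.attrs["diffuser_seed"] = ds.diffuser_seed
        f.attrs["split_seed"] = ds.manifest.seed
        f.attrs["scene"] = json.dumps(ds.scene.to_dict())


def load_dataset(path) -> SimulatedDataset:
    with h5py.File(path, "r") as f:
        manifest = DatasetManifest(
            n_total=f["stacks"].shape[0],
            per_class=f["stacks"].shape[0] // 10,
            seed=int(f.attrs["split_seed"]),
            train_ids=f["split/train"][...],
            val_ids=f["split/val"][...],
            test_ids=f["split/test"][...],
        )
        return SimulatedDataset(
            stacks=f["stacks"][...],
            truths=f["truths"][...],
            manifest=manifest,
            arm=str(f.attrs["arm"]),
            scene=SceneConfig(**json.loads(f.attrs["scene"])),
            classes=f["classes"][...],
            rotations=f["rotations"][...],
            corpus_hash=str(f.attrs["corpus_hash"]),
            diffuser_seed=int(f.attrs["diffuser_seed"]),
        )


def _arch_hash(cfg: NetworkConfig) -> str:
    return hashlib.sha256(json.dumps(cfg.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def save_checkpoint(path, model: LGDiffNet) -> None:
    """Weights as npz plus a JSON sidecar with the config and its hash."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    sidecar = {"architecture_hash": _arch_hash(model.cfg), "config": model.cfg.to_dict()}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path) -> LGDiffNet:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg_d = sidecar["config"]
    cfg_d["dilations"] = tuple(cfg_d["dilations"])
    cfg = NetworkConfig(**cfg_d)
    if _arch_hash(cfg) != sidecar["architecture_hash"]:
        raise ValueError("architecture hash mismatch in checkpoint sidecar")
    model = LGDiffNet(cfg, seed=0)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
        model.load_state_dict({k: z[k] for k in z.files})
    return model.eval()
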