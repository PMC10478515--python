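"""Dataset persistence: HDF5 (default) or NPZ with the same keys.

Layout: /images (N, H, W float32), /labels (N int8, 0=non-sample-hit,
1=single-hit, 2=multi-hit), /sample_ids, /source_ids (UTF-8 strings),
/fluence (N float64), /seeds (N int64), optional /partition (strings);
file attributes carry a JSON config blob and the master seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .simulator import INT_TO_LABEL, LABEL_TO_INT, SpecklePattern

__all__ = ["save_dataset", "load_dataset"]

_KEYS = ("images", "labels", "sample_ids", "source_ids", "fluence", "seeds")


def _columns(patterns: list[SpecklePattern]):
    unknown = {p.label for p in patterns} - set(LABEL_TO_INT)
    if unknown:
        raise ValueError(
            f"dataset files store the canonical hit classes only; "
            f"cannot encode labels {sorted(unknown)}"
        )
    return {
        "images": np.stack([p.image for p in patterns]).astype(np.float32),
        "labels": np.array([LABEL_TO_INT[p.label] for p in patterns], np.int8),
        "sample_ids": np.array([p.sample_id for p in patterns]),
        "source_ids": np.array([p.source_id for p in patterns]),
        "fluence": np.array([p.fluence_multiplier for p in patterns]),
        "seeds": np.array([p.rng_seed for p in patterns], np.int64),
        "augmented": np.array([p.is_augmented for p in patterns], np.int8),
    }


def save_dataset(path: str | Path, patterns: list[SpecklePattern],
                 config: dict | None = None,
                 partition: list[str] | None = None) -> None:
    if not patterns:
        raise ValueError("refusing to write an empty dataset")
    path = Path(path)
    cols = _columns(patterns)
    if partition is not None:
        cols["partition"] = np.array(partition)
    meta = json.dumps(config or {}, default=str)
    if path.suffix == ".npz":
        np.savez(path, __config__=meta, **cols)
        return
    with h5py.File(path, "w") as fh:
        for key, arr in cols.items():
            if arr.dtype.kind in "US":
                fh.create_dataset(key, data=arr.astype(object),
                                  dtype=h5py.string_dtype())
            else:
                fh.create_dataset(key, data=arr)
        fh.attrs["config"] = meta
        fh.attrs["label_map"] = json.dumps(LABEL_TO_INT)


def load_dataset(path: str | Path) -> tuple[list[SpecklePattern], dict]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dataset file not found: {path}")
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as archive:
            cols = {k: archive[k] for k in archive.files if k != "__config__"}
            config = json.loads(str(archive["__config__"]))
    else:
        with h5py.File(path, "r") as fh:
            cols = {}
            for key in fh:
                arr = fh[key][()]
                if arr.dtype.kind == "O" or h5py.check_string_dtype(fh[key].dtype):
                    arr = np.array([s.decode() if isinstance(s, bytes) else str(s)
                                    for s in arr])
                cols[key] = arr
            config = json.loads(fh.attrs.get("config", "{}"))
    for key in _KEYS:
        if key not in cols:
            raise ValueError(f"dataset {path} is missing /{key}")
    patterns = []
    for i in range(len(cols["images"])):
        patterns.append(SpecklePattern(
            image=cols["images"][i],
            label=INT_TO_LABEL[int(cols["labels"][i])],
            sample_id=str(cols["sample_ids"][i]),
            fluence_multiplier=float(cols["fluence"][i]),
            rng_seed=int(cols["seeds"][i]),
            is_augmented=bool(cols.get("augmented", np.zeros(1))[i])
            if "augmented" in cols else False,
            source_id=str(cols["source_ids"][i]),
        ))
    return patterns, config
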