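"""Dataset persistence: 8-bit grayscale PNGs with a CSV manifest, plus an
optional single-file compressed array container for fast loading.  The
manifest is the source of truth."""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
from PIL import Image

from .core import Dataset

MANIFEST_COLUMNS = ["filename", "split", "task", "label1", "label2",
                    "family", "seed", "index"]


def save_dataset(ds: Dataset, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(len(ds)):
        fname = f"images/{ds.split}_{i:06d}.png"
        arr = np.clip(np.asarray(ds.images[i], dtype=np.float64), 0, 1)
        Image.fromarray((arr * 255).round().astype(np.uint8), mode="L").save(
            out_dir / fname)
        labels = ds.labels[i]
        meta = ds.meta[i]
        rows.append({
            "filename": fname,
            "split": ds.split,
            "task": ds.task,
            "label1": labels[0],
            "label2": labels[1] if len(labels) > 1 else "",
            "family": meta.get("family", ""),
            "seed": meta.get("seed", ""),
            "index": meta.get("index", i),
        })
    manifest = out_dir / f"manifest_{ds.split}.csv"
    with open(manifest, "w", newline="") as f:
        writer = csv.DictWriter(f, fieldnames=MANIFEST_COLUMNS)
        writer.writeheader()
        writer.writerows(rows)
    with open(out_dir / f"meta_{ds.split}.json", "w") as f:
        json.dump(ds.meta, f, default=int)
    return manifest


def load_dataset(out_dir: str | Path, split: str = "train") -> Dataset:
    out_dir = Path(out_dir)
    manifest = out_dir / f"manifest_{split}.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest for split {split!r} in {out_dir}")
    with open(manifest, newline="") as f:
        rows = list(csv.DictReader(f))
    meta_path = out_dir / f"meta_{split}.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else [{}] * len(rows)
    images, labels = [], []
    task = rows[0]["task"] if rows else "multimnist"
    for row in rows:
        arr = np.asarray(Image.open(out_dir / row["filename"]), dtype=np.float32) / 255.0
        images.append(arr)
        if row["task"] == "reasoning":
            labels.append((row["label1"],))
        else:
            labels.append(tuple(sorted((int(row["label1"]), int(row["label2"])))))
    return Dataset(images=np.stack(images), labels=labels, meta=meta,
                   task=task, split=split)


def save_npz(ds: Dataset, path: str | Path):
    labels = np.array([",".join(str(x) for x in lab) for lab in ds.labels])
    np.savez_compressed(path, images=ds.images, labels=labels,
                        task=ds.task, split=ds.split,
                        meta=json.dumps(ds.meta, default=int))


def load_npz(path: str | Path) -> Dataset:
    data = np.load(path, allow_pickle=False)
    task = str(data["task"])
    labels = []
    for s in data["labels"]:
        parts = str(s).split(",")
        if task == "reasoning":
            labels.append(tuple(parts))
        else:
            labels.append(tuple(int(p) for p in parts))
    return Dataset(images=data["images"], labels=labels,
                   meta=json.loads(str(data["meta"])), task=task,
                   split=str(data["split"]))
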