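"""Manifest I/O, patient records, and the stratified 4/1 train/test split.

Conventions used throughout the package (stated once, here): images are
numpy arrays of shape height x width x 3 in RGB channel order with
0-based pixel indexing; label vectors are 8-entry multi-hot arrays in
the fixed order N, D, G, C, A, H, M, O (normal, diabetic retinopathy,
glaucoma, cataract, age-related macular degeneration, hypertension,
pathological myopia, other).  Labels are patient-level: both eyes of a
row share the row's label vector.

The split reserves round(n * (1 - train_ratio)) records per class for
the test set, rounding to the nearest integer (ties to even, Python's
``round``).  With the default 4/1 ratio this rule reproduces the
published per-class train/test table for the ODIR-2019 dataset exactly;
the table is bundled below as reference input data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CLASSES = ("N", "D", "G", "C", "A", "H", "M", "O")
MANIFEST_COLUMNS = ("id", "left_image", "right_image") + CLASSES

#: Published ODIR per-class sample distribution: class -> (original images,
#: preprocessed images).  Used as reference input for split arithmetic.
ODIR_TABLE = {
    "N": (2873, 2873), "D": (1608, 1539), "G": (284, 1638), "C": (293, 1674),
    "A": (266, 1560), "H": (128, 756), "M": (232, 1206), "O": (708, 1346),
}


@dataclass
class PatientRecord:
    """One patient: id, the two eye images, and the multi-hot labels."""

    id: str
    left_path: Path
    right_path: Path
    labels: np.ndarray
    provenance: tuple = ("original",)

    def __post_init__(self):
        self.left_path = Path(self.left_path)
        self.right_path = Path(self.right_path)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(CLASSES),):
            raise ValueError("labels must have exactly 8 entries")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be strictly 0/1")


@dataclass
class ManifestData:
    records: list[PatientRecord]
    errors: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def read_manifest(path, check_files: bool = True) -> ManifestData:
    """Read an ODIR-style CSV manifest.

    A missing or wrong header is a hard error; individual bad rows
    (non-binary labels, unresolvable image files) are skipped and
    reported in ``errors`` instead of aborting the whole read.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} is missing required columns: {missing}")
    base = path.parent
    records, errors = [], []
    for i, row in df.iterrows():
        labels = row[list(CLASSES)].to_numpy()
        try:
            labels = labels.astype(int)
        except (TypeError, ValueError):
            errors.append(f"row {i} (id={row['id']}): non-integer label values")
            continue
        if not np.isin(labels, (0, 1)).all():
            errors.append(f"row {i} (id={row['id']}): labels must be 0/1")
            continue
        left = base / str(row["left_image"])
        right = base / str(row["right_image"])
        if check_files:
            bad = [p for p in (left, right) if not p.is_file()]
            if bad:
                errors.append(f"row {i} (id={row['id']}): missing image file(s) "
                              + ", ".join(str(b) for b in bad))
                continue
        records.append(PatientRecord(str(row["id"]), left, right, labels))
    return ManifestData(records, errors)


def write_manifest(records, path) -> Path:
    """Write records as a CSV manifest; image paths stored relative to it."""
    path = Path(path)
    rows = []
    for r in records:
        def rel(p):
            try:
                return str(Path(p).relative_to(path.parent))
            except ValueError:
                return str(p)
        rows.append({"id": r.id, "left_image": rel(r.left_path),
                     "right_image": rel(r.right_path),
                     **{c: int(b) for c, b in zip(CLASSES, r.labels)}})
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# splitting


@dataclass
class SplitSpec:
    train_ratio: float = 0.8
    seed: int = 0
    stratified: bool = True

    def validate(self):
        if not (0.0 < self.train_ratio < 1.0):
            raise ValueError("train_ratio must be strictly between 0 and 1")


def split_counts(n: int, train_ratio: float = 0.8) -> tuple[int, int]:
    """(train, test) sizes for a class of n records: the test share is
    rounded to the nearest integer (ties to even)."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    test = round(n * (1.0 - train_ratio))
    return n - test, test


def split(records, spec: SplitSpec | None = None):
    """Stratified, seeded, leakage-free train/test split.

    Records are grouped per class (a multi-label record belongs to every
    pool of its active labels) and each class contributes its rounded
    test share.  A record already assigned through an earlier class keeps
    its assignment — no patient ever appears on both sides.  Returns
    (train, test) lists whose union is the input and intersection empty.
    """
    spec = spec or SplitSpec()
    spec.validate()
    records = list(records)
    rng = np.random.default_rng(spec.seed)
    if not spec.stratified:
        idx = rng.permutation(len(records))
        _, n_test = split_counts(len(records), spec.train_ratio)
        test_ids = set(idx[:n_test].tolist())
        train = [r for i, r in enumerate(records) if i not in test_ids]
        test = [r for i, r in enumerate(records) if i in test_ids]
        return train, test

    assignment: dict[int, str] = {}      # record index -> "train" | "test"
    for ci in range(len(CLASSES)):
        pool = [i for i, r in enumerate(records) if r.labels[ci] == 1]
        if not pool:
            continue
        _, n_test = split_counts(len(pool), spec.train_ratio)
        fixed_test = sum(1 for i in pool if assignment.get(i) == "test")
        free = [i for i in pool if i not in assignment]
        order = rng.permutation(len(free))
        take = max(0, min(n_test - fixed_test, len(free)))
        for k, oi in enumerate(order):
            assignment[free[oi]] = "test" if k < take else "train"
    # records with no active class at all (defensive; N covers healthy)
    for i in range(len(records)):
        assignment.setdefault(i, "train")
    train = [r for i, r in enumerate(records) if assignment[i] == "train"]
    test = [r for i, r in enumerate(records) if assignment[i] == "test"]
    return train, test


def split_summary(train, test) -> dict:
    """Per-class counts of a split, JSON-serializable."""
    def counts(rs):
        agg = np.zeros(len(CLASSES), dtype=int)
        for r in rs:
            agg += r.labels
        return {c: int(v) for c, v in zip(CLASSES, agg)}
    return {"train_total": len(train), "test_total": len(test),
            "train": counts(train), "test": counts(test)}
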