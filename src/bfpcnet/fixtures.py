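"""Deterministic synthetic paired fundus-like images and manifests.

Every patient gets two square RGB images (left/right eye): a bright
orange circular disc on a dark background, a few dark vessel-like
chords, and one distinct visual motif per active disease label.  The
motif catalogue (invented, intensity-separated so small models can learn
it) is:

==  ============================================================
D   6-9 small bright yellow blobs scattered inside the disc
G   an enlarged pale inner disc (oversized, near-white optic disc)
C   three thin concentric bright rings around the disc centre
    (high-frequency so it survives Gaussian background subtraction,
    unlike a pure global haze)
A   4-7 near-black round spots inside the disc
H   two red straight lines crossing the disc
M   a tilted cyan crescent near the disc edge
O   dense random magenta speckle inside the disc
N   no motif at all (set automatically when no disease is active)
==  ============================================================

Each motif owns a distinct colour band as well as a distinct shape, so
the classes stay separable after the weighted enhancement step and tiny
networks can overfit them; the images are deliberately schematic, not
photorealistic.

Labels are patient-level multi-hot vectors in the order N,D,G,C,A,H,M,O;
when ``per_eye_independence`` is set, each eye samples its own disease
bits and the patient label is their union.  Rendering is a pure function
of (spec, patient index): the per-patient random stream is spawned from
the dataset seed and the index alone, so patient i is identical no
matter how many patients are generated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .data_io import CLASSES, PatientRecord, write_manifest


@dataclass
class SyntheticSpec:
    n_patients: int = 20
    image_size: int = 64
    #: one probability per label N,D,G,C,A,H,M,O; the N entry is ignored
    #: (N is derived: it is set exactly when no disease bit is active)
    class_probabilities: tuple = (0.0, 0.22, 0.22, 0.22, 0.22, 0.22, 0.22, 0.22)
    seed: int = 0
    per_eye_independence: bool = True

    def validate(self):
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32 pixels")
        if len(self.class_probabilities) != len(CLASSES):
            raise ValueError("class_probabilities needs exactly 8 entries")
        if any(not (0.0 <= p <= 1.0) for p in self.class_probabilities):
            raise ValueError("class probabilities must lie in [0, 1]")


def _grid(s):
    y, x = np.mgrid[0:s, 0:s].astype(float)
    return y, x


def _disc_mask(s, cy, cx, r):
    y, x = _grid(s)
    return (y - cy) ** 2 + (x - cx) ** 2 <= r ** 2


def _paint(img, mask, color):
    for c in range(3):
        img[..., c][mask] = color[c]


def _render_eye(rng: np.random.Generator, size: int, bits: np.ndarray) -> np.ndarray:
    s = size
    img = rng.integers(5, 15, size=(s, s, 3)).astype(float)
    cy = cx = s / 2.0
    r = 0.45 * s
    disc = _disc_mask(s, cy, cx, r)
    y, x = _grid(s)
    rad = np.sqrt((y - cy) ** 2 + (x - cx) ** 2) / r
    base = np.stack([200 - 60 * rad, 110 - 40 * rad, 55 - 20 * rad], axis=-1)
    base += rng.normal(0, 6, size=(s, s, 3))
    img[disc] = base[disc]

    # vessel-like dark chords for texture
    for _ in range(3):
        ang = rng.uniform(0, np.pi)
        off = rng.uniform(-0.3, 0.3) * r
        d = np.abs((x - cx) * np.sin(ang) - (y - cy) * np.cos(ang) - off)
        vessel = (d < max(1.0, s / 80)) & disc
        img[vessel] *= 0.55

    def inside(margin=0.30):
        ang = rng.uniform(0, 2 * np.pi)
        rr = rng.uniform(0, (1 - margin)) * r
        return cy + rr * np.sin(ang), cx + rr * np.cos(ang)

    if bits[1]:  # D: small bright yellow blobs
        for _ in range(int(rng.integers(6, 10))):
            by, bx = inside()
            _paint(img, _disc_mask(s, by, bx, max(2.0, s / 24)), (255, 250, 60))
    if bits[2]:  # G: enlarged pale inner disc
        gy, gx = cy + rng.uniform(-0.1, 0.1) * r, cx + rng.uniform(-0.1, 0.1) * r
        _paint(img, _disc_mask(s, gy, gx, 0.40 * r), (245, 235, 215))
    if bits[3]:  # C: concentric bright rings
        dist = np.sqrt((y - cy) ** 2 + (x - cx) ** 2)
        for frac in (0.30, 0.52, 0.74):
            ring = (np.abs(dist - frac * r) < max(1.0, s / 72)) & disc
            _paint(img, ring, (235, 235, 240))
    if bits[4]:  # A: dark round spots
        for _ in range(int(rng.integers(4, 8))):
            by, bx = inside()
            _paint(img, _disc_mask(s, by, bx, max(2.5, s / 18)), (5, 2, 2))
    if bits[5]:  # H: two bright red crossing lines
        for ang in rng.uniform(0, np.pi, size=2):
            d = np.abs((x - cx) * np.sin(ang) - (y - cy) * np.cos(ang))
            line = (d < max(1.5, s / 48)) & disc
            _paint(img, line, (255, 60, 40))
    if bits[6]:  # M: tilted cyan crescent near the disc edge
        ang = rng.uniform(0, 2 * np.pi)
        my, mx = cy + 0.55 * r * np.sin(ang), cx + 0.55 * r * np.cos(ang)
        big = _disc_mask(s, my, mx, 0.42 * r)
        cut = _disc_mask(s, my + 0.18 * r * np.sin(ang + 0.8),
                         mx + 0.18 * r * np.cos(ang + 0.8), 0.38 * r)
        _paint(img, big & ~cut & disc, (70, 210, 240))
    if bits[7]:  # O: dense random magenta speckle
        n_speck = max(60, s * s // 45)
        sy = rng.integers(0, s, size=n_speck)
        sx = rng.integers(0, s, size=n_speck)
        keep = disc[sy, sx]
        img[sy[keep], sx[keep]] = (255, 60, 255)

    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _sample_bits(rng, probs):
    bits = np.zeros(len(CLASSES), dtype=int)
    for k in range(1, len(CLASSES)):
        bits[k] = int(rng.random() < probs[k])
    bits[0] = int(bits[1:].sum() == 0)
    return bits


def generate_patient(spec: SyntheticSpec, index: int):
    """Render one patient: (PatientRecord, left image, right image).

    The record's image paths are the canonical file names used by
    :func:`generate_dataset` (relative, not yet written to disk).
    """
    spec.validate()
    if not (0 <= index < spec.n_patients):
        raise ValueError(f"index {index} outside 0..{spec.n_patients - 1}")
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(index,)))
    probs = spec.class_probabilities
    left_bits = _sample_bits(rng, probs)
    right_bits = _sample_bits(rng, probs) if spec.per_eye_independence else left_bits.copy()
    patient = np.maximum(left_bits, right_bits)
    patient[0] = int(patient[1:].sum() == 0)
    left = _render_eye(rng, spec.image_size, left_bits)
    right = _render_eye(rng, spec.image_size, right_bits)
    pid = f"p{index:04d}"
    record = PatientRecord(pid, f"{pid}_left.png", f"{pid}_right.png", patient)
    return record, left, right


def generate_dataset(spec: SyntheticSpec, out_dir) -> Path:
    """Write n_patients image pairs + a manifest CSV; returns the manifest path.

    Refuses to overwrite an existing manifest.
    """
    spec.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    if manifest.exists():
        raise FileExistsError(f"{manifest} already exists; refusing to overwrite")
    records = []
    for i in range(spec.n_patients):
        record, left, right = generate_patient(spec, i)
        Image.fromarray(left).save(out_dir / record.left_path)
        Image.fromarray(right).save(out_dir / record.right_path)
        record.left_path = out_dir / record.left_path
        record.right_path = out_dir / record.right_path
        records.append(record)
    return write_manifest(records, manifest)
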