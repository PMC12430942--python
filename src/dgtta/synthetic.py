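"""Paired source/target-domain 3D phantoms with a shared label geometry.

The generator emulates a cross-modality intensity gap (CT-like source,
MR-like target): both domains render the *same* random blob geometry, but
through different per-class intensity lookups.  The target lookup is a
non-monotone remapping of the source lookup (contrast inversion for some
classes), plus an independent additive noise draw and a smooth
multiplicative bias field — deliberately a non-affine gap, because a
descriptor built from squared intensity differences is affine-invariant by
construction and would trivially close an affine gap.

Class identity is additionally encoded in intensity-invariant signatures:
each class has a characteristic blob size range and a class-specific
texture grating that is present in both domains.  Without such cues a
phantom would encode class identity *only* in absolute intensity, and no
intensity-invariant feature could ever recover it — domain-generalized
models would be untestable in principle.  Real anatomy carries exactly
these shape/texture regularities.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core import LabelMap, Volume, write_volume

# class-specific signatures: radius ranges (vox) and texture gratings
_RADIUS_RANGES = {1: (4.0, 6.0), 2: (7.0, 10.0), 3: (8.0, 11.0), 4: (5.0, 8.0)}
_TEX_FREQ = {1: 0.45, 2: 0.30, 3: 0.18, 4: 0.10}
_TEX_DIR = {1: (1.0, 0.0, 0.0), 2: (0.0, 1.0, 0.0),
            3: (0.0, 0.0, 1.0), 4: (0.577, 0.577, 0.577)}
_N_BLOBS = {1: 2, 2: 1, 3: 1, 4: 2}
_ANISO = {1: 1.0, 2: 1.2, 3: 1.8, 4: 1.0}  # axis elongation of the ellipsoids


@dataclasses.dataclass
class PhantomSpec:
    """Configuration of one paired-domain phantom.

    ``source_means``/``target_means`` list per-class mean intensities with
    the background first.  The defaults give a monotone (CT-like) source
    ramp and a non-monotone (MR-like, partially contrast-inverted) target
    map: some tissue classes keep an intensity close to their source
    appearance while others swap ranks, emulating a gap that degrades a
    source-trained model severely but not to chance level.  Class means
    must stay separated by at least twice the noise level so structures
    remain learnable within each domain.
    """

    grid_size: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)
    n_structures: int = 4
    source_means: tuple = (0.15, 0.35, 0.55, 0.75, 0.95)
    target_means: tuple = (0.10, 0.42, 0.95, 0.28, 0.75)
    noise_sigma: float = 0.05
    texture_amplitude: float = 0.10
    bias_amplitude: float = 0.15
    structure_scale: float = 1.0  # multiplies the per-class radius ranges
    margin: int = 3
    seed: int = 0

    def radius_range(self, c: int) -> tuple[float, float]:
        lo, hi = _RADIUS_RANGES[c]
        return lo * self.structure_scale, hi * self.structure_scale

    def validate(self):
        if self.n_structures < 1 or self.n_structures > 4:
            raise ValueError("n_structures must be in 1..4")
        for name, means in (("source", self.source_means), ("target", self.target_means)):
            if len(means) != self.n_structures + 1:
                raise ValueError(f"{name}_means must have background + {self.n_structures} entries")
            gaps = np.abs(np.subtract.outer(means, means))
            gaps = gaps[~np.eye(len(means), dtype=bool)]
            if self.noise_sigma > 0 and gaps.min() < 2 * self.noise_sigma:
                raise ValueError(f"{name} class means closer than 2 x noise_sigma")
        # the cross-domain map must not be affine, else the gap is trivial
        src = np.asarray(self.source_means)
        tgt = np.asarray(self.target_means)
        coef = np.polyfit(src, tgt, 1)
        resid = tgt - np.polyval(coef, src)
        if np.abs(resid).max() < 1e-3:
            raise ValueError("target intensity map is an affine function of the source map")
        max_r = max(self.radius_range(c)[1] * _ANISO[c]
                    for c in range(1, self.n_structures + 1))
        if 2 * max_r + 2 * self.margin > min(self.grid_size):
            raise ValueError("structures do not fit the grid")


def _render_geometry(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Random smooth-boundary ellipsoid blobs, painted class 1..K in order."""
    shape = spec.grid_size
    zz, yy, xx = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape],
                             indexing="ij")
    # paint big classes first so small structures are not overwritten
    order = sorted(range(1, spec.n_structures + 1),
                   key=lambda c: -np.mean(_RADIUS_RANGES[c]) * _ANISO[c])
    for _ in range(8):  # redraw until every class is present
        label = np.zeros(shape, dtype=np.int32)
        for c in order:
            lo, hi = spec.radius_range(c)
            field = np.zeros(shape)
            for _b in range(_N_BLOBS[c]):
                radii = rng.uniform(lo, hi, 3)
                radii[rng.integers(3)] *= _ANISO[c]
                m = spec.margin + radii.max()
                center = [rng.uniform(m, s - m) for s in shape]
                # random rotation of the ellipsoid axes
                q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
                rel = np.stack([zz - center[0], yy - center[1], xx - center[2]])
                rot = np.einsum("ij,jabc->iabc", q, rel)
                dist = sum((rot[i] / radii[i]) ** 2 for i in range(3))
                field = np.maximum(field, (dist <= 1.0).astype(np.float64))
            field = ndimage.gaussian_filter(field, 1.0)
            label[field > 0.5] = c
        if len(np.unique(label)) == spec.n_structures + 1:
            return label
    raise RuntimeError("failed to place all structures")


def _texture(label: np.ndarray, spec: PhantomSpec,
             rng: np.random.Generator) -> np.ndarray:
    """Class-specific gratings, identical in both domains (tissue property)."""
    shape = label.shape
    zz, yy, xx = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape],
                             indexing="ij")
    out = np.zeros(shape)
    for c in range(1, spec.n_structures + 1):
        f, d = _TEX_FREQ[c], _TEX_DIR[c]
        phase = rng.uniform(0, 2 * np.pi)
        grating = np.sin(2 * np.pi * f * (d[0] * zz + d[1] * yy + d[2] * xx) + phase)
        out[label == c] = grating[label == c]
    return out * spec.texture_amplitude


def _bias_field(shape, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field: exponentiated low-order polynomial."""
    if amplitude <= 0:
        return np.ones(shape)
    coords = np.meshgrid(*[np.linspace(-1, 1, s) for s in shape], indexing="ij")
    z, y, x = coords
    basis = [z, y, x, z * y, z * x, y * x, z * z, y * y, x * x]
    coef = rng.normal(size=len(basis))
    q = sum(c * b for c, b in zip(coef, basis))
    q = q / max(np.abs(q).max(), 1e-12)
    return np.exp(amplitude * q)


def generate_phantom(spec: PhantomSpec, rng: np.random.Generator):
    """One phantom: a label map and its source- and target-domain renderings.

    Randomness flows through named substreams (geometry, intensity, noise)
    spawned from the generator in a fixed order, so the same stream state
    always yields an identical triplet.
    """
    spec.validate()
    geom_rng, intens_rng, noise_rng = rng.spawn(3)
    label = _render_geometry(spec, geom_rng)
    tex = _texture(label, spec, intens_rng)
    bias = _bias_field(spec.grid_size, spec.bias_amplitude, intens_rng)

    src = np.asarray(spec.source_means)[label] + tex
    tgt = np.asarray(spec.target_means)[label] + tex
    tgt = tgt * bias
    if spec.noise_sigma > 0:
        src = src + noise_rng.normal(0, spec.noise_sigma, label.shape)
        tgt = tgt + noise_rng.normal(0, spec.noise_sigma, label.shape)

    lm = LabelMap(label, spec.spacing)
    return lm, Volume(src, spec.spacing), Volume(tgt, spec.spacing)


def generate_phantoms(spec: PhantomSpec, n: int, seed: int):
    """``n`` independent phantoms from per-phantom seeded streams."""
    return [generate_phantom(spec, np.random.default_rng([seed, i])) for i in range(n)]


def generate_dataset(spec: PhantomSpec, n_train: int, n_test: int, seed: int,
                     out_dir) -> dict:
    """Write a source/train, source/test, target/test NIfTI tree + manifest.

    Every phantom appears in exactly one split: the target test phantoms
    have their own geometries (the source/target ratio stays >= 2:1 with
    the defaults).  Output is uncompressed NIfTI so re-runs with the same
    seed are byte-identical.
    """
    if n_train < 1 or n_test < 1:
        raise ValueError("n_train and n_test must be >= 1")
    out_dir = Path(out_dir)
    phantoms = generate_phantoms(spec, n_train + 2 * n_test, seed)
    manifest = {"seed": seed, "spec": dataclasses.asdict(spec), "splits": {}}

    def _write(split: str, items, domain_idx: int):
        entries = []
        for pid, (lm, src, tgt) in items:
            vol = (src, tgt)[domain_idx]
            base = out_dir / split
            img_path = base / f"img_{pid}.nii"
            lab_path = base / f"lab_{pid}.nii"
            write_volume(vol, img_path)
            write_volume(lm, lab_path)
            entries.append({"id": pid, "image": str(img_path.relative_to(out_dir)),
                            "label": str(lab_path.relative_to(out_dir))})
        manifest["splits"][split] = entries

    ids = [f"s{seed}_{i:03d}" for i in range(len(phantoms))]
    _write("source/train", list(zip(ids[:n_train], phantoms[:n_train])), 0)
    _write("source/test", list(zip(ids[n_train:n_train + n_test],
                                   phantoms[n_train:n_train + n_test])), 0)
    _write("target/test", list(zip(ids[n_train + n_test:],
                                   phantoms[n_train + n_test:])), 1)
    text = json.dumps(manifest, indent=1, sort_keys=True)
    (out_dir / "manifest.json").write_text(text)
    manifest["checksum"] = hashlib.sha256(text.encode()).hexdigest()
    return manifest
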