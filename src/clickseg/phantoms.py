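"""Synthetic dual-modality phantoms with the statistical structure of
head-and-neck PET-CT tumor data.

Each phantom is a co-registered CT/PET pair with a single ground-truth tumor
blob: the CT channel carries smooth soft-tissue-scale anatomy in Hounsfield
units with additive noise; the PET channel carries a low uptake background
with elevated uptake inside the tumor plus *distractor* hot spots outside
the ground truth.  The distractors emulate metabolically active lymph nodes
— the classic false-positive mode of PET-driven tumor segmentation — so
trained models make the kind of mistakes that negative clicks correct.

Everything is fully determined by the seed in the spec, so datasets
regenerate bit-identically from their manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volumes import BinaryMask, ImageVolume, Modality, VolumePair, write_nifti
from .volumes import window_normalize_ct, zscore_normalize_pet

__all__ = ["PhantomSpec", "Phantom", "generate_phantom", "generate_dataset", "split_dataset"]


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for one phantom.

    Defaults are desk-scale: 48^3 voxels at isotropic 1 mm.  PET values are
    on an SUV-like scale (background ~1, tumor ~1 + ``pet_tumor_contrast``);
    CT values are Hounsfield-scale soft tissue.  ``distractor_count`` hot
    spots of node-like size and tumor-like uptake are placed outside the
    ground truth with a 2-voxel margin.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    spacing_mm: float = 1.0
    tumor_count: int = 1
    tumor_radius_range: tuple[float, float] = (6.0, 10.0)
    distractor_count: int = 3
    distractor_radius_range: tuple[float, float] = (2.0, 4.0)
    ct_noise_sd: float = 20.0
    pet_tumor_contrast: float = 5.0
    pet_background_level: float = 1.0
    pet_noise_sd: float = 0.3
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        for key in ("shape", "tumor_radius_range", "distractor_radius_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class Phantom:
    """One generated sample: raw volumes, normalized pair, ground truth, and
    the distractor hot-spot mask (disjoint from the ground truth)."""

    ct_raw: ImageVolume
    pet_raw: ImageVolume
    gt: BinaryMask
    distractors: BinaryMask
    spec: PhantomSpec

    @property
    def pair(self) -> VolumePair:
        return VolumePair(window_normalize_ct(self.ct_raw), zscore_normalize_pet(self.pet_raw))


def _smooth_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Band-limited random field with unit SD (Gaussian-filtered white noise)."""
    x = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = x.std()
    return x / sd if sd > 0 else x


def _lobed_blob(
    rng: np.random.Generator, shape, center, radii, lobe_amp: float = 0.35
) -> np.ndarray:
    """Randomized ellipsoid with lobed deformation.

    The implicit surface is the unit level set of the scaled squared radius
    perturbed by a smooth random field, giving irregular, lobulated tumor
    shapes rather than perfect ellipsoids.
    """
    grids = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    bump = _smooth_noise(rng, shape, sigma=3.0) * lobe_amp
    return (q + bump) < 1.0


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Generate one dual-modality phantom; deterministic in ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    H, W, D = shape

    # --- ground-truth tumor (one lobed blob near the volume center) ---
    gt = np.zeros(shape, dtype=bool)
    for _ in range(spec.tumor_count):
        center = [n / 2 + rng.uniform(-n / 8, n / 8) for n in shape]
        radii = [rng.uniform(*spec.tumor_radius_range) for _ in range(3)]
        gt |= _lobed_blob(rng, shape, center, radii)
    if not gt.any():
        raise RuntimeError("degenerate spec: empty ground-truth mask")

    # --- distractor hot spots strictly outside the ground truth ---
    margin = ndimage.binary_dilation(gt, iterations=2)
    distractors = np.zeros(shape, dtype=bool)
    for _ in range(spec.distractor_count):
        placed = False
        for _attempt in range(200):
            r = rng.uniform(*spec.distractor_radius_range)
            c = [rng.uniform(r + 1, n - r - 1) for n in shape]
            blob = _lobed_blob(rng, shape, c, [r, r, r], lobe_amp=0.2)
            if blob.any() and not (blob & margin).any():
                distractors |= blob
                placed = True
                break
        if not placed:
            raise RuntimeError(
                "could not place a distractor outside the ground truth "
                "after 200 attempts; loosen the spec"
            )

    # --- CT: smooth HU-scale anatomy + denser tumor tissue + noise ---
    ct = 40.0 + 80.0 * _smooth_noise(rng, shape, sigma=6.0)
    ct += 30.0 * gt  # tumor slightly denser than surrounding soft tissue
    ct += rng.normal(0.0, spec.ct_noise_sd, shape)
    ct = np.clip(ct, -200.0, 400.0)

    # --- PET: low background, hot tumor, node-like hot distractors, blur ---
    pet = spec.pet_background_level * (1.0 + 0.2 * _smooth_noise(rng, shape, sigma=8.0))
    pet = pet + spec.pet_tumor_contrast * gt.astype(np.float64)
    pet = pet + spec.pet_tumor_contrast * rng.uniform(0.7, 1.1) * distractors
    pet = ndimage.gaussian_filter(pet, 1.0)  # scanner point-spread blur
    pet += rng.normal(0.0, spec.pet_noise_sd, shape)
    pet = np.clip(pet, 0.0, None)

    sp = (spec.spacing_mm,) * 3
    return Phantom(
        ImageVolume(ct.astype(np.float32), sp, Modality.CT),
        ImageVolume(pet.astype(np.float32), sp, Modality.PET),
        BinaryMask(gt.astype(np.uint8), sp),
        BinaryMask(distractors.astype(np.uint8), sp),
        spec,
    )


def generate_dataset(
    n: int, spec: PhantomSpec, seed: int | None = None
) -> list[Phantom]:
    """Generate ``n`` phantoms with per-sample seeds derived from ``seed``.

    Per-sample seeds are ``SeedSequence(seed).generate_state(n)`` so the
    whole dataset is reproducible from the manifest.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if seed is None:
        seed = spec.seed
    child_seeds = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    out = []
    for s in child_seeds:
        sub = PhantomSpec(**{**spec.to_dict(), "seed": int(s)})
        out.append(generate_phantom(sub))
    return out


def split_dataset(
    dataset: list, fractions: tuple[float, float, float], seed: int = 0
) -> tuple[list, list, list]:
    """Shuffled train/val/test split honoring the requested fractions.

    Val and test sizes are ``round(f * n)``; the remainder goes to train.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(dataset)
    idx = np.random.default_rng(seed).permutation(n)
    n_val = round(fractions[1] * n)
    n_test = round(fractions[2] * n)
    n_train = n - n_val - n_test
    order = [dataset[i] for i in idx]
    return order[:n_train], order[n_train : n_train + n_val], order[n_train + n_val :]


def write_dataset(dataset: list[Phantom], out_dir: str | Path, seed: int | None = None) -> Path:
    """Write phantoms as NIfTI triples plus a JSON manifest for replay."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"n": len(dataset), "seed": seed, "samples": []}
    for i, ph in enumerate(dataset):
        stem = f"phantom_{i:04d}"
        write_nifti(ph.ct_raw, out_dir / f"{stem}_ct.nii.gz")
        write_nifti(ph.pet_raw, out_dir / f"{stem}_pet.nii.gz")
        write_nifti(ph.gt, out_dir / f"{stem}_gt.nii.gz")
        manifest["samples"].append({"stem": stem, "spec": ph.spec.to_dict()})
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir / "manifest.json"


def read_manifest(manifest_path: str | Path) -> list[Phantom]:
    """Regenerate a dataset from its manifest (bit-identical to the original)."""
    manifest = json.loads(Path(manifest_path).read_text())
    return [generate_phantom(PhantomSpec.from_dict(s["spec"])) for s in manifest["samples"]]
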