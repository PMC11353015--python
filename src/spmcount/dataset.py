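"""Hybrid labelled-dataset builder for the 11-class particle counter.

Three generation methods are mixed, mirroring how practical SPM training
sets combine physics and measurement:

* **M1** — pure simulation: random scenes rendered by the interference model
  and degraded over a grid of SNR conditions.
* **M2** — simulated particles composited onto particle-free background
  images (here synthesized: illumination gradient + correlated speckle +
  streak artifacts; the interface accepts real background crops).
* **M3** — labelled single-particle patches pasted at random positions onto
  backgrounds, emulating composites cut from real measurements.

The default per-class budget is 7000 (M1: 1000 x 7 noise conditions)
+ 1000 (M2) + 100 (M3) = 8100 images for each of the 11 count classes
(N = 0..9 plus an "others" class absorbing N > 9).  Every image's seed is
derived from the master seed, so a rebuild is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .degrade import NOISE_FREE, NoiseSpec, add_noise, blur, degrade, disk_kernel
from .optics import OpticalParams, ParticleSpec, Scene, render_scene, sample_scene

__all__ = [
    "BackgroundSpec",
    "DatasetConfig",
    "DatasetManifest",
    "ImageSample",
    "PatchLibrary",
    "gen_background",
    "make_sample_m1",
    "make_sample_m2",
    "make_sample_m3",
    "build_patch_library",
    "build_hybrid_dataset",
    "split_manifest",
    "write_images",
    "quantize_image",
    "reference_signal_power",
    "realize_record",
    "load_dataset_arrays",
]

N_CLASSES = 11
OTHERS_LABEL = 10

# namespace codes for per-record seed derivation
_NS_M1, _NS_M2, _NS_M3, _NS_BG, _NS_PATCH, _NS_REF = 1, 2, 3, 101, 102, 103


def class_label(n_particles: int) -> int:
    """Count -> class label: identity for N <= 9, 'others' (10) for N > 9."""
    if n_particles < 0:
        raise ValueError("n_particles must be >= 0")
    return min(n_particles, OTHERS_LABEL)


def derive_seed(master_seed: int, *path: int) -> int:
    """Stable per-record seed (< 2**31) from a master seed and an index path."""
    ss = np.random.SeedSequence(entropy=(int(master_seed),) + tuple(int(p) for p in path))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass(frozen=True)
class ImageSample:
    """One labelled image with its generation provenance."""

    image: np.ndarray
    n_particles: int
    label: int
    method: str  # M1 | M2 | M3
    snr_db: float
    seed: int

    def __post_init__(self) -> None:
        if self.label != class_label(self.n_particles):
            raise ValueError(
                f"label {self.label} inconsistent with n_particles "
                f"{self.n_particles} under the 0-9 + others scheme"
            )


@dataclass(frozen=True)
class BackgroundSpec:
    """Synthetic particle-free background: what real SPM backgrounds show.

    A planar illumination gradient (non-uniform intensity and incidence
    angle across the field of view), band-limited Gaussian speckle with the
    given correlation length, and 1-D streaks (vibration motion artifacts)
    running along ``streak_direction``.  Amplitudes are relative to the
    unit plasmonic background intensity.
    """

    gradient_amplitude: float = 0.08
    speckle_amplitude: float = 0.04
    speckle_correlation_length: float = 6.0
    streak_amplitude: float = 0.02
    streak_direction: str = "horizontal"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gradient_amplitude", "speckle_amplitude", "streak_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.speckle_correlation_length <= 0:
            raise ValueError("speckle_correlation_length must be > 0")
        if self.streak_direction not in ("horizontal", "vertical"):
            raise ValueError(f"bad streak_direction {self.streak_direction!r}")


def gen_background(spec: BackgroundSpec, shape: tuple[int, int]) -> np.ndarray:
    """Render one synthetic background image of the given (rows, cols) shape."""
    rows, cols = shape
    rng = np.random.default_rng(spec.seed)
    img = np.ones((rows, cols))

    theta = rng.uniform(0, 2 * math.pi)
    yy, xx = np.mgrid[0:rows, 0:cols]
    if spec.gradient_amplitude > 0:
        ramp = (xx * math.cos(theta) + yy * math.sin(theta))
        ramp = ramp - ramp.mean()
        span = ramp.max() - ramp.min()
        if span > 0:
            img += spec.gradient_amplitude * ramp / span
    if spec.speckle_amplitude > 0:
        white = rng.normal(0, 1, (rows, cols))
        # Gaussian filter sigma = l/2 gives an autocovariance exp(-r^2/l^2)
        # with 1/e width l = speckle_correlation_length
        sm = ndimage.gaussian_filter(white, spec.speckle_correlation_length / 2.0,
                                     mode="wrap")
        sm_std = sm.std()
        if sm_std > 0:
            img += spec.speckle_amplitude * sm / sm_std
    if spec.streak_amplitude > 0:
        n_lines = rows if spec.streak_direction == "horizontal" else cols
        line = ndimage.gaussian_filter1d(rng.normal(0, 1, n_lines), 1.5,
                                         mode="wrap")
        line_std = line.std()
        if line_std > 0:
            line = spec.streak_amplitude * line / line_std
        if spec.streak_direction == "horizontal":
            img += line[:, None]
        else:
            img += line[None, :]
    return img


@dataclass
class PatchLibrary:
    """Labelled particle crops used by Method 3 compositing."""

    patches: list[tuple[np.ndarray, int]]
    config: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.patches)


@dataclass(frozen=True)
class DatasetConfig:
    """Full generation recipe; hashable, JSON-serializable, seeds excluded."""

    optics: OpticalParams = field(default_factory=OpticalParams)
    noise_grid: tuple[float, ...] = (NOISE_FREE, 30.0, 25.0, 20.0, 15.0, 8.0, 1.0)
    m1_per_condition: int = 1000
    m2_per_class: int = 1000
    m3_per_class: int = 100
    others_range: tuple[int, int] = (10, 14)  # inclusive draw range for N > 9
    amplitude_range: tuple[float, float] = (0.2, 1.0)
    position_margin: float = 4.0
    blur_radius: float = 1.0
    background: BackgroundSpec = field(default_factory=BackgroundSpec)
    n_backgrounds: int = 300
    n_patches: int = 200
    patch_side: int = 24
    patch_snr_db: float = 30.0
    degrade_m2: bool = True
    degrade_m3: bool = False
    signal_power_policy: str = "clean_image_variance"

    @property
    def per_class_total(self) -> int:
        return (self.m1_per_condition * len(self.noise_grid)
                + self.m2_per_class + self.m3_per_class)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["noise_grid"] = [_snr_str(s) for s in self.noise_grid]
        return d

    def config_hash(self, master_seed: int) -> str:
        payload = json.dumps({"config": self.to_dict(), "master_seed": master_seed},
                             sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "DatasetConfig":
        d = dict(d)
        opt = dict(d.pop("optics", {}))
        opt.pop("units", None)
        for key in ("prop_direction", "image_shape"):
            if key in opt:
                opt[key] = tuple(opt[key])
        d["optics"] = OpticalParams(**opt)
        d["background"] = BackgroundSpec(**d.pop("background", {}))
        if "noise_grid" in d:
            d["noise_grid"] = tuple(_snr_from_str(str(s)) for s in d["noise_grid"])
        for key in ("others_range", "amplitude_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _snr_str(snr: float) -> str:
    return "noise_free" if snr == NOISE_FREE else repr(float(snr))


def _snr_from_str(s: str) -> float:
    return NOISE_FREE if s == "noise_free" else float(s)


@dataclass
class DatasetManifest:
    """Record table (one row per image) plus the recipe that produced it.

    Columns: path, n_particles, label, method, snr_db, seed, bg_index, split.
    """

    records: pd.DataFrame
    config: DatasetConfig
    master_seed: int

    @property
    def config_hash(self) -> str:
        return self.config.config_hash(self.master_seed)

    def per_class_counts(self) -> pd.Series:
        return self.records.groupby("label").size()

    def per_method_counts(self) -> pd.DataFrame:
        return self.records.groupby(["label", "method"]).size().unstack(fill_value=0)

    def split_counts(self) -> pd.DataFrame:
        return self.records.groupby(["label", "split"]).size().unstack(fill_value=0)

    def to_csv(self, path: str | Path) -> None:
        df = self.records.copy()
        df["snr_db"] = [_snr_str(s) for s in df["snr_db"]]
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, config: DatasetConfig,
                 master_seed: int) -> "DatasetManifest":
        df = pd.read_csv(path, keep_default_na=False)
        df["snr_db"] = [_snr_from_str(str(s)) for s in df["snr_db"]]
        return cls(records=df, config=config, master_seed=master_seed)

    def manifest_digest(self) -> str:
        """Hash of the full record table; equal digests mean identical manifests."""
        df = self.records.copy()
        df["snr_db"] = [_snr_str(s) for s in df["snr_db"]]
        blob = df.to_csv(index=False).encode()
        return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# sample generators (Methods 1-3)
# ---------------------------------------------------------------------------

def _noise_seed(seed: int) -> int:
    # decorrelate the noise stream from the scene stream of the same record
    return (seed * 2654435761 + 0x9E3779B9) % (2**31)


def reference_signal_power(
    optics: OpticalParams,
    blur_radius: float = 1.0,
    amplitude_range: tuple[float, float] = (0.2, 1.0),
    seed: int = 0,
    n_probe: int = 20,
) -> float:
    """Mean variance of blurred single-particle renders.

    Serves as the instrument-level signal power when a blank (constant)
    image needs finite-SNR noise: the noise floor is a property of the
    detector, not of the particle count.
    """
    kernel = disk_kernel(blur_radius)
    powers = []
    for i in range(n_probe):
        scene = sample_scene(1, optics, amplitude_range=amplitude_range,
                             rng_seed=derive_seed(seed, _NS_REF, i))
        powers.append(float(np.var(blur(render_scene(scene), kernel))))
    return float(np.mean(powers))


def make_sample_m1(
    n: int,
    snr: NoiseSpec,
    optics: OpticalParams,
    seed: int,
    position_margin: float = 4.0,
    amplitude_range: tuple[float, float] = (0.2, 1.0),
) -> ImageSample:
    """Method 1: pure simulation (random scene -> render -> blur -> noise)."""
    scene = sample_scene(n, optics, position_margin, amplitude_range, rng_seed=seed)
    img = degrade(render_scene(scene),
                  dataclasses.replace(snr, seed=_noise_seed(seed)))
    return ImageSample(image=img, n_particles=n, label=class_label(n),
                       method="M1", snr_db=snr.snr_db, seed=seed)


def make_sample_m2(
    n: int,
    background: np.ndarray,
    optics: OpticalParams,
    snr: NoiseSpec,
    seed: int,
    position_margin: float = 4.0,
    amplitude_range: tuple[float, float] = (0.2, 1.0),
    apply_degradation: bool = True,
) -> ImageSample:
    """Method 2: simulated particles composited onto a background image.

    The zero-mean interference term (render minus the flat E0^2 background)
    is added onto the supplied background, so a flat unit background
    reproduces Method 1 exactly.
    """
    background = np.asarray(background, dtype=float)
    if background.shape != optics.image_shape:
        raise ValueError(
            f"background shape {background.shape} != render grid {optics.image_shape}"
        )
    scene = sample_scene(n, optics, position_margin, amplitude_range, rng_seed=seed)
    interference = render_scene(scene) - optics.background_amplitude**2
    img = background + interference
    if apply_degradation:
        img = degrade(img, dataclasses.replace(snr, seed=_noise_seed(seed)))
    return ImageSample(image=img, n_particles=n, label=class_label(n),
                       method="M2", snr_db=snr.snr_db, seed=seed)


def build_patch_library(
    n_patches: int,
    optics: OpticalParams | None = None,
    amplitude_range: tuple[float, float] = (0.2, 1.0),
    patch_side: int = 24,
    seed: int = 0,
    snr_db: float = 30.0,
) -> PatchLibrary:
    """Crop single-particle windows from high-SNR renders, each labelled n=1."""
    if n_patches < 1:
        raise ValueError("n_patches must be >= 1")
    if optics is None:
        optics = OpticalParams()
    rows, cols = optics.image_shape
    if patch_side >= min(rows, cols):
        raise ValueError(f"patch_side {patch_side} exceeds render grid {optics.image_shape}")
    patches: list[tuple[np.ndarray, int]] = []
    half = patch_side // 2
    for i in range(n_patches):
        pseed = derive_seed(seed, _NS_PATCH, i)
        rng = np.random.default_rng(pseed)
        # particle near the grid centre with sub-pixel jitter
        cy, cx = rows // 2, cols // 2
        pos = ((cx + rng.uniform(-0.5, 0.5)) * optics.pixel_pitch,
               (cy + rng.uniform(-0.5, 0.5)) * optics.pixel_pitch)
        particle = ParticleSpec(position=pos,
                                amplitude=rng.uniform(*amplitude_range),
                                phase=rng.uniform(0, 2 * math.pi))
        scene = Scene(params=optics, particles=(particle,), seed=pseed)
        img = degrade(render_scene(scene), NoiseSpec(snr_db=snr_db, seed=pseed))
        patch = img[cy - half:cy - half + patch_side,
                    cx - half:cx - half + patch_side].copy()
        patches.append((patch, 1))
    return PatchLibrary(patches=patches,
                        config={"n_patches": n_patches, "patch_side": patch_side,
                                "snr_db": _snr_str(snr_db), "seed": seed})


def _border_mean(patch: np.ndarray) -> float:
    return float(np.mean(np.concatenate([
        patch[0], patch[-1], patch[1:-1, 0], patch[1:-1, -1]])))


def make_sample_m3(
    n: int,
    library: PatchLibrary,
    background: np.ndarray,
    seed: int,
) -> ImageSample:
    """Method 3: paste labelled patches onto a background at random positions.

    Each paste adds (patch - patch-border-mean) into the target window so
    the patch blends into the local background level; overlapping pastes
    accumulate additively.  Patches are drawn until their labels sum to n.
    """
    if len(library) == 0:
        raise ValueError("patch library is empty")
    background = np.asarray(background, dtype=float)
    img = background.copy()
    rng = np.random.default_rng(seed)
    rows, cols = img.shape
    remaining = n
    pasted = 0
    while remaining > 0:
        eligible = [i for i, (_, lab) in enumerate(library.patches)
                    if lab <= remaining]
        if not eligible:
            raise ValueError(
                f"no patch combination sums to {n} (remaining {remaining})")
        idx = eligible[rng.integers(len(eligible))]
        patch, lab = library.patches[idx]
        ph, pw = patch.shape
        if ph > rows or pw > cols:
            raise ValueError("patch larger than background")
        r0 = int(rng.integers(0, rows - ph + 1))
        c0 = int(rng.integers(0, cols - pw + 1))
        img[r0:r0 + ph, c0:c0 + pw] += patch - _border_mean(patch)
        remaining -= lab
        pasted += lab
    return ImageSample(image=img, n_particles=pasted, label=class_label(pasted),
                       method="M3", snr_db=NOISE_FREE, seed=seed)


# ---------------------------------------------------------------------------
# full hybrid-dataset orchestration
# ---------------------------------------------------------------------------

def _plan_records(config: DatasetConfig, master_seed: int) -> pd.DataFrame:
    rows = []
    lo, hi = config.others_range

    def particle_count(label: int, seed: int) -> int:
        if label < OTHERS_LABEL:
            return label
        return int(np.random.default_rng(seed).integers(lo, hi + 1))

    for label in range(N_CLASSES):
        idx = 0
        for cond, snr in enumerate(config.noise_grid):
            for i in range(config.m1_per_condition):
                seed = derive_seed(master_seed, _NS_M1, label, cond, i)
                n = particle_count(label, seed)
                rows.append((f"images/class{label:02d}/M1_{idx:06d}.png",
                             n, label, "M1", snr, seed, -1))
                idx += 1
        for i in range(config.m2_per_class):
            seed = derive_seed(master_seed, _NS_M2, label, 0, i)
            rng = np.random.default_rng(seed)
            snr = config.noise_grid[rng.integers(len(config.noise_grid))]
            bg = int(rng.integers(config.n_backgrounds))
            n = particle_count(label, seed)
            rows.append((f"images/class{label:02d}/M2_{idx:06d}.png",
                         n, label, "M2", snr, seed, bg))
            idx += 1
        for i in range(config.m3_per_class):
            seed = derive_seed(master_seed, _NS_M3, label, 0, i)
            rng = np.random.default_rng(seed)
            bg = int(rng.integers(config.n_backgrounds))
            n = particle_count(label, seed)
            rows.append((f"images/class{label:02d}/M3_{idx:06d}.png",
                         n, label, "M3", NOISE_FREE, seed, bg))
            idx += 1
    df = pd.DataFrame(rows, columns=["path", "n_particles", "label", "method",
                                     "snr_db", "seed", "bg_index"])
    df["split"] = "unsplit"
    return df


def build_hybrid_dataset(config: DatasetConfig | None = None,
                         master_seed: int = 0) -> DatasetManifest:
    """Plan the full hybrid dataset as a manifest (images rendered lazily).

    Counts, labels, seeds, noise conditions and background assignments are
    all fixed here; pixel data are produced on demand by
    :func:`realize_record` / :func:`write_images`, so count bookkeeping is
    cheap even at the full 8100-per-class scale.
    """
    if config is None:
        config = DatasetConfig()
    records = _plan_records(config, master_seed)
    return DatasetManifest(records=records, config=config, master_seed=master_seed)


class _Realizer:
    """Caches backgrounds, the patch library and the blank-image signal power."""

    def __init__(self, config: DatasetConfig, master_seed: int):
        self.config = config
        self.master_seed = master_seed
        self._backgrounds: dict[int, np.ndarray] = {}
        self._library: PatchLibrary | None = None
        self._blank_power: float | None = None

    def background(self, idx: int) -> np.ndarray:
        if idx not in self._backgrounds:
            spec = dataclasses.replace(
                self.config.background,
                seed=derive_seed(self.master_seed, _NS_BG, idx))
            self._backgrounds[idx] = gen_background(spec,
                                                    self.config.optics.image_shape)
        return self._backgrounds[idx]

    @property
    def library(self) -> PatchLibrary:
        if self._library is None:
            self._library = build_patch_library(
                self.config.n_patches, self.config.optics,
                self.config.amplitude_range, self.config.patch_side,
                seed=derive_seed(self.master_seed, _NS_PATCH),
                snr_db=self.config.patch_snr_db)
        return self._library

    @property
    def blank_power(self) -> float:
        if self._blank_power is None:
            self._blank_power = reference_signal_power(
                self.config.optics, self.config.blur_radius,
                self.config.amplitude_range,
                seed=derive_seed(self.master_seed, _NS_REF))
        return self._blank_power

    def realize(self, record) -> ImageSample:
        cfg = self.config
        n = int(record.n_particles)
        snr = float(record.snr_db)
        seed = int(record.seed)
        # blank clean images have zero variance; scale their noise to the
        # instrument-level reference power instead
        override = self.blank_power if (n == 0 and snr != NOISE_FREE) else None
        spec = NoiseSpec(snr_db=snr, blur_radius=cfg.blur_radius,
                         signal_power=override)
        if record.method == "M1":
            return make_sample_m1(n, spec, cfg.optics, seed,
                                  cfg.position_margin, cfg.amplitude_range)
        if record.method == "M2":
            return make_sample_m2(n, self.background(int(record.bg_index)),
                                  cfg.optics, spec, seed, cfg.position_margin,
                                  cfg.amplitude_range,
                                  apply_degradation=cfg.degrade_m2)
        if record.method == "M3":
            sample = make_sample_m3(n, self.library,
                                    self.background(int(record.bg_index)), seed)
            if cfg.degrade_m3:
                img = degrade(sample.image,
                              dataclasses.replace(spec, seed=_noise_seed(seed)))
                sample = dataclasses.replace(sample, image=img)
            return sample
        raise ValueError(f"unknown method {record.method!r}")


def realize_record(record, config: DatasetConfig, master_seed: int) -> ImageSample:
    """Render the pixels of one manifest record (standalone convenience)."""
    return _Realizer(config, master_seed).realize(record)


def load_dataset_arrays(
    manifest: DatasetManifest,
    split: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Realize (images, labels) arrays straight from a manifest, no file I/O."""
    realizer = _Realizer(manifest.config, manifest.master_seed)
    df = manifest.records
    if split is not None:
        df = df[df["split"] == split]
    images = np.stack([realizer.realize(rec).image
                       for rec in df.itertuples(index=False)])
    labels = df["label"].to_numpy(dtype=int)
    return images, labels


def split_manifest(manifest: DatasetManifest,
                   ratio: tuple[int, int, int] = (8, 1, 1),
                   seed: int = 0) -> DatasetManifest:
    """Per-class stratified train/val/test split.

    Rounding: floor for val and test, remainder to train (8:1:1 on a class
    of 8100 gives 6480/810/810).
    """
    if min(ratio) <= 0:
        raise ValueError("split ratio parts must be positive")
    total = sum(ratio)
    df = manifest.records.copy()
    df["split"] = "train"
    rng = np.random.default_rng(seed)
    for label, group in df.groupby("label"):
        if len(group) < 10:
            raise ValueError(f"class {label} has {len(group)} < 10 records")
        order = group.index.to_numpy()[rng.permutation(len(group))]
        n_val = int(len(group) * ratio[1] // total)
        n_test = int(len(group) * ratio[2] // total)
        df.loc[order[:n_val], "split"] = "val"
        df.loc[order[n_val:n_val + n_test], "split"] = "test"
    return DatasetManifest(records=df, config=manifest.config,
                           master_seed=manifest.master_seed)


def quantize_image(image: np.ndarray) -> np.ndarray:
    """Per-image min-max normalization to [0, 255] uint8; constant -> 128."""
    image = np.asarray(image, dtype=float)
    lo, hi = float(image.min()), float(image.max())
    # a span at float rounding level (e.g. |e^{i*phase}|^2 ripple) is constant
    if hi - lo <= 1e-9 * max(abs(lo), abs(hi), 1.0):
        return np.full(image.shape, 128, dtype=np.uint8)
    scaled = (image - lo) * (255.0 / (hi - lo))
    return np.round(scaled).astype(np.uint8)


def sample_to_png_array(image: np.ndarray, out_size: int = 224) -> np.ndarray:
    """Quantize, bilinear-resize to out_size and replicate to 3 channels."""
    q = quantize_image(image)
    resized = np.asarray(
        Image.fromarray(q, mode="L").resize((out_size, out_size),
                                            Image.Resampling.BILINEAR))
    return np.repeat(resized[:, :, None], 3, axis=2)


def write_images(manifest: DatasetManifest, out_dir: str | Path,
                 out_size: int = 224) -> Path:
    """Write every record as a 3-channel PNG plus CSV manifest and config JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    realizer = _Realizer(manifest.config, manifest.master_seed)
    for rec in manifest.records.itertuples(index=False):
        sample = realizer.realize(rec)
        arr = sample_to_png_array(sample.image, out_size)
        path = out_dir / rec.path
        path.parent.mkdir(parents=True, exist_ok=True)
        Image.fromarray(arr, mode="RGB").save(path)
    manifest.to_csv(out_dir / "manifest.csv")
    sidecar = {"config": manifest.config.to_dict(),
               "master_seed": manifest.master_seed,
               "config_hash": manifest.config_hash,
               "pipeline_order": "blur_then_noise",
               "out_size": out_size}
    (out_dir / "config.json").write_text(json.dumps(sidecar, indent=2))
    return out_dir
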