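"""Synthetic slide cohorts with sparse-lesion structure.

A digitized whole-slide image is modelled as a bag of fixed-size RGB patches
on a grid.  A *positive* slide carries a minority fraction of lesion-textured
patches among background-textured ones; a negative slide carries none.  The
two textures are separable by a small CNN but share the same mean intensity,
so brightness alone carries no class signal:

* background — low-spatial-frequency Gaussian blobs plus pixel noise,
  mimicking loosely structured stroma;
* lesion — high-frequency oriented stripes plus pixel noise, mimicking the
  dense, directional patterning of tumour regions.

Each slide additionally receives a small global intensity offset (staining /
exposure variation between slides).  The offset shifts every patch of a slide
coherently, which perturbs slide-level score *pooling* but not the
within-slide score *ranking* — the regime the top-K representation is
designed for.

Survival times follow a proportional-hazards model on lesion burden (the
fraction of lesion patches in the slide) with an exponential baseline and
independent exponential censoring calibrated to a target censoring rate.

Cohorts are a pure function of (spec, seed): identical specs reproduce
byte-identical pixel arrays.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image
from scipy.optimize import brentq
from skimage.transform import resize

__all__ = [
    "TextureParams",
    "SyntheticCohortSpec",
    "Patch",
    "Slide",
    "generate_cohort",
    "generate_survival",
    "write_cohort",
    "read_slide_dir",
]


@dataclass(frozen=True)
class TextureParams:
    """Descriptors for the two texture families, intensities in [0, 1] units.

    ``blob_cells`` is the number of low-resolution noise cells across a
    background patch (lower = smoother blobs); ``stripe_cycles`` the number of
    stripe periods across a lesion patch.
    """

    base_intensity: float = 0.60
    blob_cells: int = 4
    blob_amplitude: float = 0.15
    stripe_cycles: float = 8.0
    stripe_amplitude: float = 0.15
    noise_sd: float = 0.10
    slide_intensity_sd: float = 0.05
    #: mean fraction of background patches carrying weak stripes
    #: (inflammation / fibrosis-like regions that draw intermediate scores);
    #: the realised rate varies per slide (Beta-distributed), so slides differ
    #: in how much confounding tissue they contain
    confounder_fraction: float = 0.15
    #: Beta concentration of the per-slide confounder rate (lower = more
    #: slide-to-slide spread)
    confounder_concentration: float = 1.2
    #: stripe amplitude of confounder patches relative to true lesions
    confounder_amplitude_ratio: float = 0.6
    #: per-slide lesion/confounder severity multiplier range (uniform draw):
    #: some slides carry faint lesions, others florid ones
    severity_range: tuple[float, float] = (0.5, 1.3)
    #: per-slide pixel-noise multiplier range (uniform draw): slide-to-slide
    #: scan quality variation
    noise_multiplier_range: tuple[float, float] = (0.7, 1.6)

    def validate(self) -> None:
        if not 0.0 <= self.base_intensity <= 1.0:
            raise ValueError("texture_params.base_intensity must be in [0, 1]")
        if self.noise_sd < 0 or self.noise_sd > 1:
            raise ValueError("texture_params.noise_sd must be in [0, 1]")
        if self.blob_cells < 2:
            raise ValueError("texture_params.blob_cells must be >= 2")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Full parameterisation of a synthetic cohort.

    ``lesion_fraction`` is the proportion of patches in a positive slide that
    carry lesion texture; a positive slide always receives at least one.
    ``hazard_coef`` is the log-hazard per unit lesion burden and
    ``baseline_scale`` the baseline mean survival in months.
    """

    n_slides_pos: int = 10
    n_slides_neg: int = 10
    patches_per_slide_range: tuple[int, int] = (12, 24)
    lesion_fraction: float = 0.1
    patch_size: int = 64
    texture_params: TextureParams = field(default_factory=TextureParams)
    hazard_coef: float = 2.0
    baseline_scale: float = 60.0
    censoring_rate: float = 0.3
    n_classes: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_slides_pos < 0:
            raise ValueError("n_slides_pos must be >= 0")
        if self.n_slides_neg < 0:
            raise ValueError("n_slides_neg must be >= 0")
        lo, hi = self.patches_per_slide_range
        if lo < 1 or hi < lo:
            raise ValueError("patches_per_slide_range must satisfy 1 <= min <= max")
        if not 0.0 < self.lesion_fraction <= 1.0:
            raise ValueError("lesion_fraction must be in (0, 1]")
        if self.patch_size < 8:
            raise ValueError("patch_size must be >= 8")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must be in [0, 1)")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.baseline_scale <= 0:
            raise ValueError("baseline_scale must be > 0")
        self.texture_params.validate()


@dataclass
class Patch:
    image: np.ndarray  # (H, W, 3) float32 RGB in [0, 1]
    grid_row: int
    grid_col: int


@dataclass
class Slide:
    """One slide: ordered patches with grid coordinates plus outcome fields."""

    slide_id: str
    patches: list[Patch]
    label: Optional[int] = None
    time: Optional[float] = None
    event: Optional[int] = None
    patch_truth: Optional[list[bool]] = None

    def __post_init__(self) -> None:
        coords = [(p.grid_row, p.grid_col) for p in self.patches]
        if len(set(coords)) != len(coords):
            raise ValueError(f"slide {self.slide_id}: duplicate grid coordinates")
        sizes = {p.image.shape for p in self.patches}
        if len(sizes) > 1:
            raise ValueError(f"slide {self.slide_id}: patches of mixed sizes {sizes}")
        if (self.time is None) != (self.event is None):
            raise ValueError(f"slide {self.slide_id}: time and event must be "
                             "present together")

    @property
    def n_patches(self) -> int:
        return len(self.patches)

    @property
    def lesion_burden(self) -> float:
        if self.patch_truth is None:
            raise ValueError(f"slide {self.slide_id}: no patch_truth available")
        return float(np.mean(self.patch_truth)) if self.patch_truth else 0.0

    def patch_array(self) -> np.ndarray:
        """All patches stacked as (N, H, W, 3) float32."""
        return np.stack([p.image for p in self.patches]).astype(np.float32)


# ---------------------------------------------------------------------------
# texture synthesis
# ---------------------------------------------------------------------------


_CHANNEL_TINT = np.array([0.02, -0.02, 0.01])  # faint fixed tint, eosin-ish


def _to_rgb(gray: np.ndarray) -> np.ndarray:
    rgb = gray[:, :, None] + _CHANNEL_TINT[None, None, :]
    return np.clip(rgb, 0.0, 1.0).astype(np.float32)


def _stripes(rng: np.random.Generator, size: int, cycles: float,
             orientation: Optional[float]) -> np.ndarray:
    theta = rng.uniform(0.0, np.pi) if orientation is None \
        else orientation + rng.normal(0.0, np.pi / 24)
    phase = rng.uniform(0.0, 2 * np.pi)
    yy, xx = np.mgrid[0:size, 0:size] / size
    return np.sin(2 * np.pi * cycles
                  * (xx * np.cos(theta) + yy * np.sin(theta)) + phase)


def _confounder_rate(rng: np.random.Generator, tp: TextureParams) -> float:
    """Per-slide rate of confounder background patches."""
    f = tp.confounder_fraction
    if f <= 0:
        return 0.0
    a = tp.confounder_concentration
    return float(rng.beta(a, a * (1.0 - f) / f))


def _background_patch(rng: np.random.Generator, size: int, tp: TextureParams,
                      offset: float, confounder_rate: float) -> np.ndarray:
    cells = rng.standard_normal((tp.blob_cells, tp.blob_cells))
    blobs = resize(cells, (size, size), order=3, mode="reflect",
                   anti_aliasing=False)
    sd = blobs.std()
    if sd > 0:
        blobs = blobs / sd * tp.blob_amplitude
    gray = (tp.base_intensity + offset + blobs
            + rng.normal(0.0, tp.noise_sd, (size, size)))
    # a minority of background patches carry weak stripes: structured tissue
    # (inflammation, fibrosis) that attracts intermediate scorer output
    if confounder_rate > 0 and rng.random() < confounder_rate:
        amp = tp.stripe_amplitude * tp.confounder_amplitude_ratio
        gray = gray + amp * _stripes(rng, size, tp.stripe_cycles, None)
    return _to_rgb(gray)


def _lesion_patch(rng: np.random.Generator, size: int, tp: TextureParams,
                  offset: float, orientation: Optional[float]) -> np.ndarray:
    carrier = _stripes(rng, size, tp.stripe_cycles, orientation)
    gray = (tp.base_intensity + offset + tp.stripe_amplitude * carrier
            + rng.normal(0.0, tp.noise_sd, (size, size)))
    return _to_rgb(gray)


def _class_orientation(label: int, n_classes: int) -> Optional[float]:
    # binary cohorts use free orientation; subtype cohorts encode the class
    # in the dominant stripe direction so subtypes are mutually separable
    if n_classes <= 2:
        return None
    return (label - 1) * np.pi / (n_classes - 1)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _lesion_count(lesion_fraction: float, n_patches: int) -> int:
    # round() with a floor of 1 so a positive slide always carries signal
    return max(1, int(round(lesion_fraction * n_patches)))


def _make_slide(slide_id: str, label: int, n_patches: int, spec: SyntheticCohortSpec,
                rng: np.random.Generator) -> Slide:
    tp = spec.texture_params
    offset = rng.normal(0.0, tp.slide_intensity_sd)
    # slide-level nuisance draws: severity of striped tissue, scan noise,
    # confounder load — coherent across all patches of the slide
    severity = rng.uniform(*tp.severity_range)
    noise_mult = rng.uniform(*tp.noise_multiplier_range)
    tp = dataclasses.replace(tp, stripe_amplitude=tp.stripe_amplitude * severity,
                             noise_sd=min(1.0, tp.noise_sd * noise_mult))
    conf_rate = _confounder_rate(rng, tp)
    n_lesion = _lesion_count(spec.lesion_fraction, n_patches) if label > 0 else 0
    lesion_idx = set(rng.choice(n_patches, size=n_lesion, replace=False).tolist())
    orientation = _class_orientation(label, spec.n_classes)
    ncol = int(np.ceil(np.sqrt(n_patches)))
    patches, truth = [], []
    for i in range(n_patches):
        if i in lesion_idx:
            img = _lesion_patch(rng, spec.patch_size, tp, offset, orientation)
            truth.append(True)
        else:
            img = _background_patch(rng, spec.patch_size, tp, offset, conf_rate)
            truth.append(False)
        patches.append(Patch(img, grid_row=i // ncol, grid_col=i % ncol))
    return Slide(slide_id=slide_id, patches=patches, label=label, patch_truth=truth)


def generate_cohort(spec: SyntheticCohortSpec) -> list[Slide]:
    """Generate ``n_slides_pos + n_slides_neg`` slides, negatives first.

    With ``n_classes > 2`` the positive slides are distributed round-robin
    over classes 1..n_classes-1; class 0 is the lesion-free class.
    """
    spec.validate()
    root = np.random.default_rng(np.random.SeedSequence(spec.seed))
    lo, hi = spec.patches_per_slide_range
    slides: list[Slide] = []
    n_total = spec.n_slides_neg + spec.n_slides_pos
    counts = root.integers(lo, hi + 1, size=n_total)
    child_seeds = np.random.SeedSequence(spec.seed).spawn(n_total + 1)[1:]
    for i in range(spec.n_slides_neg):
        rng = np.random.default_rng(child_seeds[i])
        slides.append(_make_slide(f"neg_{i:04d}", 0, int(counts[i]), spec, rng))
    for j in range(spec.n_slides_pos):
        i = spec.n_slides_neg + j
        rng = np.random.default_rng(child_seeds[i])
        label = 1 + (j % (spec.n_classes - 1))
        slides.append(_make_slide(f"pos_{j:04d}", label, int(counts[i]), spec, rng))
    return slides


# ---------------------------------------------------------------------------
# survival outcomes
# ---------------------------------------------------------------------------


def _censoring_rate_for_mu(mu: float, lam: np.ndarray) -> float:
    # P(C < T) for independent exponentials with rates mu (censor), lam (event)
    return float(np.mean(mu / (mu + lam)))


def generate_survival(slides: Sequence[Slide], spec: SyntheticCohortSpec) -> list[Slide]:
    """Attach proportional-hazards survival outcomes driven by lesion burden.

    Event times are exponential with rate exp(hazard_coef * burden) /
    baseline_scale.  Censoring times are exponential with a single rate
    calibrated (by root finding) so the expected censored fraction over the
    cohort equals ``censoring_rate``.  Returns the same slide objects with
    ``time``/``event`` set.
    """
    spec.validate()
    for s in slides:
        if s.patch_truth is None:
            raise ValueError(f"slide {s.slide_id}: patch_truth required for "
                             "survival generation")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x53]))
    burdens = np.array([s.lesion_burden for s in slides])
    lam = np.exp(spec.hazard_coef * burdens) / spec.baseline_scale
    times = rng.exponential(1.0 / lam)
    if spec.censoring_rate == 0.0:
        for s, t in zip(slides, times):
            s.time, s.event = float(t), 1
        return list(slides)
    # calibrate the censoring rate mu on a log grid bracket
    f = lambda log_mu: _censoring_rate_for_mu(np.exp(log_mu), lam) - spec.censoring_rate
    log_mu = brentq(f, np.log(lam.min()) - 20.0, np.log(lam.max()) + 20.0)
    censor = rng.exponential(np.exp(-log_mu), size=len(times))
    for s, t, c in zip(slides, times, censor):
        s.time = float(min(t, c))
        s.event = int(t <= c)
    return list(slides)


# ---------------------------------------------------------------------------
# on-disk layout: per-slide PNG directories + manifest TSV
# ---------------------------------------------------------------------------


def write_cohort(slides: Sequence[Slide], outdir: str | Path) -> Path:
    """Write slides as directories of ``r{row}_c{col}.png`` patches plus a
    cohort manifest TSV; returns the manifest path."""
    from .manifest import atomic_write_text  # local import avoids a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = ["slide_id\tpath\tlabel\ttime\tevent\tn_patches"]
    for s in slides:
        sdir = outdir / s.slide_id
        sdir.mkdir(exist_ok=True)
        for p in s.patches:
            img8 = (np.clip(p.image, 0, 1) * 255).round().astype(np.uint8)
            Image.fromarray(img8).save(sdir / f"r{p.grid_row}_c{p.grid_col}.png")
        if s.patch_truth is not None:
            flags = "".join("1" if t else "0" for t in s.patch_truth)
            atomic_write_text(sdir / "patch_truth.txt", flags + "\n")
        rows.append("\t".join([
            s.slide_id,
            s.slide_id,
            "" if s.label is None else str(s.label),
            "" if s.time is None else f"{s.time:.6g}",
            "" if s.event is None else str(s.event),
            str(s.n_patches),
        ]))
    manifest = outdir / "manifest.tsv"
    atomic_write_text(manifest, "\n".join(rows) + "\n")
    return manifest


def read_slide_dir(slide_dir: str | Path, slide_id: str | None = None,
                   label: Optional[int] = None, time: Optional[float] = None,
                   event: Optional[int] = None) -> Slide:
    """Load a slide written by :func:`write_cohort` (PNG patch directory)."""
    slide_dir = Path(slide_dir)
    patches = []
    for png in sorted(slide_dir.glob("r*_c*.png")):
        stem = png.stem  # r{row}_c{col}
        r_part, c_part = stem.split("_")
        img = np.asarray(Image.open(png), dtype=np.float32) / 255.0
        patches.append(Patch(img, int(r_part[1:]), int(c_part[1:])))
    patches.sort(key=lambda p: (p.grid_row, p.grid_col))
    truth = None
    truth_file = slide_dir / "patch_truth.txt"
    if truth_file.exists():
        flags = truth_file.read_text().strip()
        truth = [ch == "1" for ch in flags]
    return Slide(slide_id=slide_id or slide_dir.name, patches=patches,
                 label=label, time=time, event=event, patch_truth=truth)
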