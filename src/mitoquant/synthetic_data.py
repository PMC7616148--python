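"""Seeded synthetic data with known ground truth.

Everything downstream of image acquisition is testable against simulation:
this module draws two-channel mito-QC tissue micrographs (correlated
red+green mitochondrial texture over an irregular tissue blob, red-only
GFP-quenched puncta from a homogeneous point process), 2x2 genotype cohorts
with configurable main and interaction effects on mitolysosome density,
two-region muscle cross-sections, gene-by-sample expression matrices with an
elevated pathway-gene tissue, and immunoblot densitometry tables.

All generators are deterministic given their seed: the same parameters
produce bit-identical images and tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from mitoquant.micrograph import MAX_INTENSITY_16BIT, Micrograph

#: Genes of the PINK1/Parkin mitophagy pathway used for tissue ranking.
PATHWAY_GENES = ("PINK1", "PRKN", "TBK1", "OPTN", "SQSTM1")

#: Hindlimb muscles ordered by increasing oxidative capacity.
MUSCLES = ("WGC", "RCM", "SOL")

# Log-amplitude of the smooth multiplicative mitochondrial texture shared by
# the red and green channels (lognormal sigma on tissue intensity).
_TEXTURE_LOG_SD = 0.15
_TEXTURE_SMOOTH_SIGMA_PX = 6.0


def _positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be > 0, got {value}")


def _fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class SynthImageParams:
    """Parameters of one synthetic two-channel tissue micrograph.

    Intensity defaults are placeholders: the reporter's optical logic (GFP
    quenched inside mitolysosomes, mCherry retained) is what matters, not
    absolute counts, and no intensity statistics exist for real
    mitolysosomes. ``quench_factor`` (default 0.1) and ``puncta_red_gain``
    (default 1.5) are configurable for that reason.
    """

    image_size_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.1
    tissue_fraction: float = 0.75
    mito_green_mean: float = 8000.0
    mito_red_mean: float = 8000.0
    background_mean: float = 200.0
    puncta_density_per_mm2: float = 5000.0
    puncta_radius_um_range: tuple[float, float] = (0.3, 0.7)
    quench_factor: float = 0.1
    puncta_red_gain: float = 1.5
    noise_sigma: float = 120.0
    poisson_noise: bool = True
    population_fraction: float = 0.0
    #: When > 0, puncta disks are rejection-sampled to be pairwise separated
    #: by at least this gap (centre distance > r_i + r_j + gap), yielding
    #: disjoint puncta whose merged count equals the true count.
    puncta_min_gap_um: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size_px
        if not (isinstance(h, (int, np.integer)) and isinstance(w, (int, np.integer))) or h <= 0 or w <= 0:
            raise ValueError(f"image_size_px must be positive integers, got {self.image_size_px}")
        _positive("pixel_size_um", self.pixel_size_um)
        _fraction("tissue_fraction", self.tissue_fraction)
        for name in ("mito_green_mean", "mito_red_mean", "background_mean"):
            v = getattr(self, name)
            if not 0 <= v <= MAX_INTENSITY_16BIT:
                raise ValueError(f"{name} must be in [0, {MAX_INTENSITY_16BIT}], got {v}")
        if self.puncta_density_per_mm2 < 0:
            raise ValueError(f"puncta_density_per_mm2 must be >= 0, got {self.puncta_density_per_mm2}")
        rmin, rmax = self.puncta_radius_um_range
        _positive("puncta_radius_um_range min", rmin)
        if rmax < rmin:
            raise ValueError(f"puncta_radius_um_range max must be >= min, got {self.puncta_radius_um_range}")
        if not 0.0 <= self.quench_factor < 1.0:
            raise ValueError(f"quench_factor must be in [0, 1), got {self.quench_factor}")
        if self.puncta_red_gain < 1.0:
            raise ValueError(f"puncta_red_gain must be >= 1, got {self.puncta_red_gain}")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        _fraction("population_fraction", self.population_fraction)
        if self.puncta_min_gap_um < 0:
            raise ValueError(f"puncta_min_gap_um must be >= 0, got {self.puncta_min_gap_um}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["image_size_px"] = list(d["image_size_px"])
        d["puncta_radius_um_range"] = list(d["puncta_radius_um_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthImageParams":
        d = dict(d)
        if "image_size_px" in d:
            d["image_size_px"] = tuple(int(v) for v in d["image_size_px"])
        if "puncta_radius_um_range" in d:
            d["puncta_radius_um_range"] = tuple(float(v) for v in d["puncta_radius_um_range"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Exact description of the pre-noise simulated scene.

    ``merged_count`` is the number of 8-connected components of the union of
    rasterized puncta disks: overlapping disks fuse into structures no
    detector can separate, so exact-count validation compares against the
    merged count (equal to ``true_count`` when puncta are disjoint).
    """

    puncta: list[tuple[float, float, float]]  # (center_row_px, center_col_px, radius_px)
    tissue_mask: np.ndarray
    population_mask: np.ndarray | None
    tissue_area_mm2: float
    true_count: int
    true_occupied_fraction: float
    merged_count: int
    puncta_mask: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.true_count != len(self.puncta):
            raise ValueError("true_count must equal number of puncta")


@dataclass(frozen=True)
class CohortDesign:
    """A 2x2 genotype cohort (PINK1 WT/KO x POLG WT/D257A) over muscle types.

    Group mean mitolysosome density is
    ``baseline[muscle] * pink1_ko_multiplier^[KO] * polg_multiplier^[D257A]
    * interaction_multiplier^[KO and D257A]``; each animal's true density is
    drawn lognormally around the group mean (median = group mean), and
    ``images_per_animal`` micrographs are simulated per animal at that
    density. Defaults encode the qualitative in-vivo pattern: oxidative
    muscles have more basal mitophagy (WGC < RCM < SOL), PINK1 loss reduces
    it, the mutator allele mildly raises it, and the double mutant returns
    to the wild-type level (interaction = 1 / (pink1 * polg)).
    """

    muscles: tuple[str, ...] = ("SOL",)
    n_per_group: int = 5
    images_per_animal: int = 12
    baseline_density_per_mm2: dict = field(
        default_factory=lambda: {"WGC": 2000.0, "RCM": 5000.0, "SOL": 8000.0}
    )
    pink1_ko_multiplier: float = 0.4
    polg_multiplier: float = 1.1
    interaction_multiplier: float = 1.0 / (0.4 * 1.1)
    animal_sd: float = 0.15
    image_params: SynthImageParams = field(
        default_factory=lambda: SynthImageParams(image_size_px=(256, 256), pixel_size_um=0.2)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError(
                f"n_per_group must be >= 2 for a factorial ANOVA to have residual "
                f"degrees of freedom, got {self.n_per_group}"
            )
        if self.images_per_animal < 1:
            raise ValueError(f"images_per_animal must be >= 1, got {self.images_per_animal}")
        for name in ("pink1_ko_multiplier", "polg_multiplier", "interaction_multiplier"):
            _positive(name, getattr(self, name))
        if self.animal_sd < 0:
            raise ValueError(f"animal_sd must be >= 0, got {self.animal_sd}")
        for m in self.muscles:
            if m not in self.baseline_density_per_mm2:
                raise ValueError(f"no baseline density for muscle {m!r}")

    def group_density(self, muscle: str, pink1: str, polg: str) -> float:
        """Mean mitolysosome density (per mm^2) for one genotype cell."""
        d = self.baseline_density_per_mm2[muscle]
        if pink1 == "KO":
            d *= self.pink1_ko_multiplier
        if polg == "D257A":
            d *= self.polg_multiplier
        if pink1 == "KO" and polg == "D257A":
            d *= self.interaction_multiplier
        return d

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["muscles"] = list(d["muscles"])
        d["image_params"] = self.image_params.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortDesign":
        d = dict(d)
        if "muscles" in d:
            d["muscles"] = tuple(d["muscles"])
        if "image_params" in d:
            d["image_params"] = SynthImageParams.from_dict(d["image_params"])
        return cls(**d)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Standardized low-pass Gaussian noise field.

    For large correlation lengths the field is drawn on a coarse grid and
    upsampled, which is equivalent up to interpolation and much cheaper
    than filtering at full resolution.
    """
    factor = max(1, int(sigma // 8))
    if factor > 1:
        coarse_shape = (shape[0] // factor + 3, shape[1] // factor + 3)
        coarse = ndimage.gaussian_filter(rng.standard_normal(coarse_shape), sigma=sigma / factor)
        field_ = ndimage.zoom(coarse, factor, order=1)[: shape[0], : shape[1]]
    else:
        field_ = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def _tissue_blob(rng: np.random.Generator, shape: tuple[int, int], fraction: float) -> np.ndarray:
    """Irregular tissue mask covering ~`fraction` of the frame, holes filled."""
    if fraction == 0.0:
        return np.zeros(shape, dtype=bool)
    if fraction == 1.0:
        return np.ones(shape, dtype=bool)
    f = _smooth_field(rng, shape, sigma=min(shape) / 8.0)
    mask = f >= np.quantile(f, 1.0 - fraction)
    # Hole-fill at generation time so the mask is exactly recoverable by
    # threshold-then-fill segmentation (no enclosed background lakes).
    return ndimage.binary_fill_holes(mask)


def _apply_noise(
    clean: np.ndarray, rng: np.random.Generator, poisson: bool, sigma: float
) -> np.ndarray:
    """Camera model: shot noise on the clean scene, then additive read noise,
    then clipping to the 16-bit range."""
    img = rng.poisson(clean).astype(np.float64) if poisson else clean.astype(np.float64)
    if sigma > 0:
        img = img + rng.normal(0.0, sigma, size=img.shape)
    return np.clip(np.rint(img), 0, MAX_INTENSITY_16BIT).astype(np.uint16)


def _place_puncta(
    rng: np.random.Generator,
    tissue: np.ndarray,
    n: int,
    radii_px: np.ndarray,
    min_gap_px: float,
) -> list[tuple[float, float, float]]:
    """Draw puncta centres uniformly over the eroded tissue mask.

    Erosion by (max radius + 2) keeps every disk strictly inside tissue, so
    quenched puncta are always enclosed holes of the green tissue signal.
    """
    if n == 0:
        return []
    margin = int(np.ceil(radii_px.max())) + 2
    eligible = ndimage.binary_erosion(tissue, structure=np.ones((3, 3)), iterations=margin)
    if not eligible.any():
        eligible = tissue
    rows, cols = np.nonzero(eligible)
    puncta: list[tuple[float, float, float]] = []
    for i in range(n):
        r = float(radii_px[i])
        for _attempt in range(5000):
            j = int(rng.integers(len(rows)))
            cy, cx = float(rows[j]), float(cols[j])
            if min_gap_px > 0 and any(
                np.hypot(cy - py, cx - px) <= r + pr + min_gap_px for py, px, pr in puncta
            ):
                continue
            puncta.append((cy, cx, r))
            break
        else:
            raise RuntimeError(
                f"could not place punctum {i + 1}/{n} with min gap {min_gap_px} px; "
                "lower the density or the gap"
            )
    return puncta


def _rasterize_disks(shape: tuple[int, int], puncta: list[tuple[float, float, float]]) -> np.ndarray:
    union = np.zeros(shape, dtype=bool)
    for cy, cx, r in puncta:
        r_int = int(np.ceil(r))
        y0, y1 = int(cy) - r_int, int(cy) + r_int + 1
        x0, x1 = int(cx) - r_int, int(cx) + r_int + 1
        y0c, x0c = max(y0, 0), max(x0, 0)
        y1c, x1c = min(y1, shape[0]), min(x1, shape[1])
        ys = np.arange(y0c, y1c)[:, None]
        xs = np.arange(x0c, x1c)[None, :]
        disk = (ys - cy) ** 2 + (xs - cx) ** 2 <= r**2
        union[y0c:y1c, x0c:x1c] |= disk
    return union


def generate_tissue_image(params: SynthImageParams) -> tuple[Micrograph, GroundTruth]:
    """Simulate one mito-QC tissue micrograph and its exact ground truth.

    The clean scene is built first (tissue blob, shared multiplicative
    mitochondrial texture on both reporter channels, red-enhanced /
    green-quenched puncta disks from a homogeneous Poisson point process
    over the tissue), the ground truth records that scene exactly, and
    noise (Poisson then Gaussian, clipped to 16 bits) is applied last.
    """
    shape = tuple(params.image_size_px)
    rng = np.random.default_rng(params.seed)

    tissue = _tissue_blob(rng, shape, params.tissue_fraction)
    texture = np.exp(_TEXTURE_LOG_SD * _smooth_field(rng, shape, _TEXTURE_SMOOTH_SIGMA_PX))

    population = None
    if params.population_fraction > 0 and tissue.any():
        f = _smooth_field(rng, shape, sigma=min(shape) / 10.0)
        thr = np.quantile(f[tissue], 1.0 - params.population_fraction)
        population = tissue & (f >= thr)

    tissue_area_mm2 = float(tissue.sum()) * params.pixel_size_um**2 * 1e-6
    expected = params.puncta_density_per_mm2 * tissue_area_mm2
    n = int(rng.poisson(expected)) if expected > 0 else 0
    rmin, rmax = params.puncta_radius_um_range
    radii_px = rng.uniform(rmin, rmax, size=n) / params.pixel_size_um
    gap_px = params.puncta_min_gap_um / params.pixel_size_um
    puncta = _place_puncta(rng, tissue, n, radii_px, gap_px) if tissue.any() else []
    puncta_mask = _rasterize_disks(shape, puncta)

    green = np.full(shape, float(params.background_mean))
    red = np.full(shape, float(params.background_mean))
    green[tissue] = params.mito_green_mean * texture[tissue]
    red[tissue] = params.mito_red_mean * texture[tissue]
    green[puncta_mask] *= params.quench_factor
    red[puncta_mask] *= params.puncta_red_gain
    green = np.clip(green, 0, MAX_INTENSITY_16BIT)
    red = np.clip(red, 0, MAX_INTENSITY_16BIT)

    label = None
    if population is not None:
        label = np.full(shape, 100.0)
        label[population] = 5000.0

    occupied = float(puncta_mask.sum()) / float(tissue.sum()) if tissue.any() else 0.0
    merged = int(ndimage.label(puncta_mask, structure=np.ones((3, 3)))[1])
    truth = GroundTruth(
        puncta=puncta,
        tissue_mask=tissue,
        population_mask=population,
        tissue_area_mm2=tissue_area_mm2,
        true_count=len(puncta),
        true_occupied_fraction=occupied,
        merged_count=merged,
        puncta_mask=puncta_mask,
    )

    green_n = _apply_noise(green, rng, params.poisson_noise, params.noise_sigma)
    red_n = _apply_noise(red, rng, params.poisson_noise, params.noise_sigma)
    label_n = (
        _apply_noise(label, rng, params.poisson_noise, params.noise_sigma)
        if label is not None
        else None
    )
    micro = Micrograph(
        green=green_n,
        red=red_n,
        label=label_n,
        pixel_size_um=params.pixel_size_um,
    )
    return micro, truth


GENOTYPE_LEVELS = {"PINK1": ("WT", "KO"), "POLG": ("WT", "D257A")}


def generate_cohort(
    design: CohortDesign,
) -> tuple[list[tuple[Micrograph, GroundTruth, dict]], pd.DataFrame]:
    """Simulate a full factorial cohort of tissue micrographs.

    Returns the list of ``(micrograph, ground_truth, labels)`` triples
    (labels: animal_id, PINK1, POLG, muscle, image_id) and a table of true
    per-animal densities suitable for direct factorial analysis.
    """
    rng = np.random.default_rng(design.seed)
    items: list[tuple[Micrograph, GroundTruth, dict]] = []
    rows = []
    for muscle in design.muscles:
        for pink1 in GENOTYPE_LEVELS["PINK1"]:
            for polg in GENOTYPE_LEVELS["POLG"]:
                gdens = design.group_density(muscle, pink1, polg)
                for a in range(design.n_per_group):
                    animal_id = f"{muscle}_{pink1}_{polg}_{a + 1}"
                    dens = gdens * (
                        float(np.exp(rng.normal(0.0, design.animal_sd)))
                        if design.animal_sd > 0
                        else 1.0
                    )
                    rows.append(
                        {
                            "animal_id": animal_id,
                            "PINK1": pink1,
                            "POLG": polg,
                            "muscle": muscle,
                            "true_density_per_mm2": dens,
                        }
                    )
                    for i in range(design.images_per_animal):
                        p = replace(
                            design.image_params,
                            puncta_density_per_mm2=dens,
                            seed=int(rng.integers(2**31)),
                        )
                        micro, truth = generate_tissue_image(p)
                        image_id = f"{animal_id}_img{i + 1:02d}"
                        micro.image_id = image_id
                        labels = {
                            "image_id": image_id,
                            "animal_id": animal_id,
                            "PINK1": pink1,
                            "POLG": polg,
                            "muscle": muscle,
                        }
                        items.append((micro, truth, labels))
    return items, pd.DataFrame(rows)


def generate_muscle_section(
    image_size_px: tuple[int, int] = (512, 512),
    pixel_size_um: float = 2.0,
    tissue_fraction: float = 0.6,
    wgc_fraction: float = 0.7,
    wgc_green_mean: float = 1500.0,
    rcm_green_mean: float = 9000.0,
    background_mean: float = 150.0,
    noise_sigma: float = 80.0,
    seed: int = 0,
) -> tuple[Micrograph, dict]:
    """Simulate a low-magnification calf cross-section with two fiber regions.

    The glycolytic white gastrocnemius (low reporter expression, fraction
    ``wgc_fraction`` of the tissue) and the oxidative red/mixed region (high
    expression) are split by a smooth spatial field, mimicking the
    mitochondrial-content contrast used to delineate the regions on
    tile scans. Returns the micrograph and a ground-truth dict with the
    region masks and true fractions.
    """
    if not 0.0 <= wgc_fraction <= 1.0:
        raise ValueError(f"wgc_fraction must be in [0, 1], got {wgc_fraction}")
    shape = tuple(image_size_px)
    rng = np.random.default_rng(seed)
    tissue = _tissue_blob(rng, shape, tissue_fraction)
    split = _smooth_field(rng, shape, sigma=min(shape) / 6.0)
    if tissue.any():
        thr = np.quantile(split[tissue], wgc_fraction)
        wgc = tissue & (split <= thr)
    else:
        wgc = np.zeros(shape, dtype=bool)
    rcm = tissue & ~wgc
    texture = np.exp(_TEXTURE_LOG_SD * _smooth_field(rng, shape, _TEXTURE_SMOOTH_SIGMA_PX))
    green = np.full(shape, float(background_mean))
    green[wgc] = wgc_green_mean * texture[wgc]
    green[rcm] = rcm_green_mean * texture[rcm]
    red = green.copy()  # reporter expressed in both channels outside mitolysosomes
    green_n = _apply_noise(np.clip(green, 0, MAX_INTENSITY_16BIT), rng, True, noise_sigma)
    red_n = _apply_noise(np.clip(red, 0, MAX_INTENSITY_16BIT), rng, True, noise_sigma)
    micro = Micrograph(green=green_n, red=red_n, pixel_size_um=pixel_size_um)
    truth = {
        "tissue_mask": tissue,
        "wgc_mask": wgc,
        "rcm_mask": rcm,
        "wgc_fraction": float(wgc.sum()) / float(tissue.sum()) if tissue.any() else 0.0,
    }
    return micro, truth


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample tissue labels."""

    values: pd.DataFrame  # index: gene ids, columns: sample ids
    tissues: pd.Series  # sample id -> tissue label
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        missing = [s for s in self.values.columns if s not in self.tissues.index]
        if missing:
            raise ValueError(f"samples without tissue label: {missing[:5]}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    def samples_per_tissue(self) -> pd.Series:
        return self.tissues.loc[self.values.columns].value_counts()


def generate_expression_matrix(
    n_tissues: int,
    samples_per_tissue: list[int],
    elevated_tissue: str | None = None,
    elevation_factor: float = 3.0,
    seed: int = 0,
    n_background_genes: int = 195,
) -> ExpressionMatrix:
    """Simulate a bulk expression matrix with pathway genes elevated in one tissue.

    Genes have lognormal baseline expression; the five mitophagy pathway
    genes are multiplied by ``elevation_factor`` in ``elevated_tissue``
    before per-sample lognormal noise. Tissues are named ``tissue_01`` ...
    unless ``elevated_tissue`` names one of them explicitly.
    """
    if len(samples_per_tissue) != n_tissues:
        raise ValueError(
            f"samples_per_tissue has {len(samples_per_tissue)} entries for {n_tissues} tissues"
        )
    if not elevation_factor > 0:
        raise ValueError(f"elevation_factor must be > 0, got {elevation_factor}")
    rng = np.random.default_rng(seed)
    tissue_names = [f"tissue_{i + 1:02d}" for i in range(n_tissues)]
    if elevated_tissue is not None and elevated_tissue not in tissue_names:
        raise ValueError(f"elevated_tissue {elevated_tissue!r} not among {tissue_names}")
    genes = list(PATHWAY_GENES) + [f"GENE{i + 1:04d}" for i in range(n_background_genes)]
    base = rng.lognormal(mean=3.0, sigma=1.0, size=len(genes))
    # mild tissue-specific expression shifts for every gene
    tissue_shift = rng.lognormal(mean=0.0, sigma=0.2, size=(len(genes), n_tissues))

    cols = {}
    tissues = {}
    for t_idx, (tname, n_samp) in enumerate(zip(tissue_names, samples_per_tissue)):
        mean = base * tissue_shift[:, t_idx]
        if elevated_tissue == tname and elevation_factor != 1.0:
            mean = mean.copy()
            mean[: len(PATHWAY_GENES)] *= elevation_factor
        for s in range(n_samp):
            sample_id = f"{tname}_s{s + 1:03d}"
            noise = rng.lognormal(mean=0.0, sigma=0.35, size=len(genes))
            cols[sample_id] = mean * noise
            tissues[sample_id] = tname
    values = pd.DataFrame(cols, index=genes)
    return ExpressionMatrix(values=values, tissues=pd.Series(tissues))


def generate_blot_table(
    reference_group: str = "WT_WT",
    group_means: dict | None = None,
    n_per_group: int = 5,
    lane_cv: float = 0.2,
    band_cv: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-lane densitometry readouts for a 2x2 immunoblot.

    Each lane gets a loading scale (lognormal, CV ``lane_cv``) applied to
    both the band and the whole-lane total-protein reference, so the
    band/lane ratio cancels loading as whole-lane normalization assumes.
    """
    if group_means is None:
        group_means = {"WT_WT": 1.0, "KO_WT": 1.8, "WT_D257A": 1.1, "KO_D257A": 1.5}
    if reference_group not in group_means:
        raise ValueError(f"reference_group {reference_group!r} not in group_means")
    rng = np.random.default_rng(seed)
    rows = []
    for group, mean in group_means.items():
        pink1, polg = group.split("_")
        for i in range(n_per_group):
            loading = rng.lognormal(0.0, lane_cv)
            true_level = mean * rng.lognormal(0.0, band_cv)
            rows.append(
                {
                    "sample_id": f"{group}_{i + 1}",
                    "group": group,
                    "PINK1": pink1,
                    "POLG": polg,
                    "band_intensity": 10000.0 * true_level * loading,
                    "lane_reference": 50000.0 * loading,
                }
            )
    return pd.DataFrame(rows)
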