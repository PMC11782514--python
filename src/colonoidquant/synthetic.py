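"""Ground-truthed synthetic inputs for every pipeline stage.

Each generator renders a raster the corresponding analysis stage can
consume *and* returns a :class:`SceneTruth` whose table is sufficient to
compute the stage's expected output without re-reading pixels. Fixed
seeds fully determine the output (integer/rounding-stable paths only),
so regression tests are bit-reproducible.

What is emulated, per stage:

* brightfield wells — bright background with dark-rimmed ellipsoidal
  colonoids of heavy-tailed (log-normal) size, some touching the image
  border, matching the polarity the local thresholding stage expects;
* H-DAB sections — RGB composed by Beer-Lambert mixing
  ``I = I0 * 10^(-M c)`` from known per-pixel hematoxylin/DAB density,
  with a known fraction of DAB-positive nuclei;
* fluorescence sections — 8-bit DAPI/KI67/CK20/TUNEL channels with
  planted nucleus classes, perinuclear CK20 rings and diffuse TUNEL
  patches;
* immunoblot tables — band intensities with known per-condition fold
  changes over a GAPDH loading control;
* chemokine panels — log-normal concentrations with donor random
  intercepts, condition/oxygen/interaction effects and lower-limit
  censoring to the "OOR <" token.

The default well density (60-120 objects) is a deliberately scaled-down
rendition of a full well so the whole suite stays fast; the morphometry
statistics are density-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import draw

from .design import Condition
from .imgio import RasterImage, StainVectors

__all__ = [
    "SceneTruth",
    "PanelSimConfig",
    "generate_brightfield_well",
    "generate_ihc_section",
    "generate_fluorescence_section",
    "simulate_chemokine_panel",
    "simulate_blot_table",
    "FLUO_CLASSES",
]


@dataclass
class SceneTruth:
    """Ground truth for one synthetic scene.

    ``objects`` lists every planted object with its id, centroid,
    rasterized area (exact pixel count × calibration²) and any class
    labels / per-channel means; ``label_mask`` is the planted label
    image (0 = background) for pixel-level oracles; ``meta`` carries
    scene-level truths such as total TUNEL area.
    """

    objects: pd.DataFrame
    calibration: float
    seed: int
    label_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# brightfield wells
# --------------------------------------------------------------------------


def generate_brightfield_well(
    n_objects: int,
    size_distribution: tuple[float, float] = (4.1, 0.35),
    calibration: float = 2.0,
    seed: int = 0,
    shape: tuple[int, int] = (768, 768),
    edge_fraction: float = 0.1,
    background: int = 220,
    rim_intensity: int = 60,
    lumen_intensity: int = 170,
    rim_width_px: int = 3,
    noise_sd: float = 2.0,
) -> tuple[RasterImage, SceneTruth]:
    """Render a stitched-well brightfield image of dark-rimmed colonoids.

    Sizes are log-normal on the equivalent diameter in µm
    (``size_distribution`` = (mean, sigma) of log diameter); objects are
    ellipses with a dark rim and a lighter lumen on a bright background.
    ``edge_fraction`` of the objects are planted straddling the image
    border; the truth table flags them so edge-exclusion rules can be
    verified exactly.
    """
    if calibration <= 0:
        raise ValueError("calibration must be > 0 µm/px")
    if n_objects < 0:
        raise ValueError("n_objects must be >= 0")
    rng = np.random.default_rng(seed)
    h, w = shape
    canvas = np.full(shape, background, dtype=np.float64)
    labels = np.zeros(shape, dtype=np.int32)

    mu, sigma = size_distribution
    records = []
    placed: list[tuple[float, float, float]] = []  # (row, col, outer radius px)
    n_edge = int(round(edge_fraction * n_objects))
    oid = 0
    attempts = 0
    max_attempts = 200 * max(n_objects, 1)
    while oid < n_objects and attempts < max_attempts:
        attempts += 1
        diam_um = float(np.exp(rng.normal(mu, sigma)))
        r_px = max(diam_um / 2.0 / calibration, 6.0)
        r_px = min(r_px, min(h, w) / 6.0)
        ecc = rng.uniform(0.8, 1.0)
        a, b = r_px / ecc, r_px * ecc
        rot = rng.uniform(0, np.pi)
        rmax = max(a, b)
        if oid < n_edge:
            # straddle a border: centre within the object's radius of one edge
            side = rng.integers(0, 4)
            off = rng.uniform(-0.5 * rmax, 0.5 * rmax)
            if side == 0:
                cy, cx = off, rng.uniform(rmax + 2, w - rmax - 2)
            elif side == 1:
                cy, cx = h - 1 - off, rng.uniform(rmax + 2, w - rmax - 2)
            elif side == 2:
                cy, cx = rng.uniform(rmax + 2, h - rmax - 2), off
            else:
                cy, cx = rng.uniform(rmax + 2, h - rmax - 2), w - 1 - off
        else:
            cy = rng.uniform(rmax + 2, h - rmax - 2)
            cx = rng.uniform(rmax + 2, w - rmax - 2)
        if any(np.hypot(cy - py, cx - px) < rmax + pr + 6 for py, px, pr in placed):
            continue
        rr, cc = draw.ellipse(cy, cx, a, b, shape=shape, rotation=rot)
        if rr.size == 0:
            continue
        inner_a, inner_b = max(a - rim_width_px, 1.0), max(b - rim_width_px, 1.0)
        ir, ic = draw.ellipse(cy, cx, inner_a, inner_b, shape=shape, rotation=rot)
        canvas[rr, cc] = rim_intensity
        canvas[ir, ic] = lumen_intensity
        oid += 1
        labels[rr, cc] = oid
        touches = bool(
            rr.min() == 0 or rr.max() == h - 1 or cc.min() == 0 or cc.max() == w - 1
        )
        records.append(
            {
                "id": oid,
                "row": cy,
                "col": cx,
                "area_px": int(rr.size),
                "area_um2": rr.size * calibration**2,
                "analytic_area_um2": np.pi * a * b * calibration**2,
                "equiv_diam_px": 2.0 * np.sqrt(rr.size / np.pi),
                "touches_edge": touches,
            }
        )
        placed.append((cy, cx, rmax))
    if oid < n_objects:
        raise RuntimeError(
            f"could only place {oid}/{n_objects} objects; reduce density or enlarge shape"
        )

    if noise_sd > 0:
        canvas = canvas + rng.normal(0.0, noise_sd, size=shape)
    pixels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    columns = [
        "id", "row", "col", "area_px", "area_um2", "analytic_area_um2",
        "equiv_diam_px", "touches_edge",
    ]
    truth = SceneTruth(
        objects=pd.DataFrame(records, columns=columns),
        calibration=calibration,
        seed=seed,
        label_mask=labels,
    )
    image = RasterImage(pixels, ("BF",), calibration)
    return image, truth


# --------------------------------------------------------------------------
# H-DAB sections
# --------------------------------------------------------------------------


def _jittered_grid(n: int, spacing: float, jitter: float, rng) -> tuple[np.ndarray, tuple[int, int]]:
    """Cell centres on a jittered grid guaranteeing minimum separation."""
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    margin = spacing
    centres = []
    for i in range(rows):
        for j in range(cols):
            if len(centres) >= n:
                break
            cy = margin + i * spacing + rng.uniform(-jitter, jitter)
            cx = margin + j * spacing + rng.uniform(-jitter, jitter)
            centres.append((cy, cx))
    h = int(margin + rows * spacing)
    w = int(margin + cols * spacing)
    return np.array(centres), (h, w)


def generate_ihc_section(
    n_cells: int,
    dab_positive_fraction: float,
    stain_vectors: StainVectors | None = None,
    seed: int = 0,
    calibration: float = 0.5,
    nucleus_radius_um: tuple[float, float] = (3.2, 4.4),
    hematoxylin_od: float = 0.7,
    tissue_od: float = 0.25,
    dab_od: float = 0.5,
) -> tuple[RasterImage, SceneTruth]:
    """Synthesize an H-DAB stained section by Beer-Lambert mixing.

    Nuclei (hematoxylin density ``hematoxylin_od``) sit inside a tissue
    region of faint hematoxylin; an exact fraction of them additionally
    carry DAB at ``dab_od`` (chromogenic positivity). The RGB composite
    is ``I = round(255 * 10^(-M c)) - 1`` so the package's OD transform
    inverts it up to 8-bit quantization.
    """
    if not 0.0 <= dab_positive_fraction <= 1.0:
        raise ValueError("dab_positive_fraction must be in [0, 1]")
    vectors = stain_vectors or StainVectors()
    m = vectors.matrix()  # validates rank
    rng = np.random.default_rng(seed)

    r_px_max = nucleus_radius_um[1] / calibration
    spacing = 2 * r_px_max + 8
    centres, (h, w) = _jittered_grid(n_cells, spacing, jitter=2.0, rng=rng)

    hema = np.zeros((h, w))
    dab = np.zeros((h, w))
    labels = np.zeros((h, w), dtype=np.int32)

    # faint tissue hematoxylin over the full cell field so the region
    # segmenter has a structure to find
    tissue_rr, tissue_cc = draw.ellipse(h / 2, w / 2, h / 2 - 2, w / 2 - 2, shape=(h, w))
    hema[tissue_rr, tissue_cc] = tissue_od

    n_pos = int(round(dab_positive_fraction * n_cells))
    pos_ids = set(rng.permutation(n_cells)[:n_pos] + 1)

    records = []
    for idx, (cy, cx) in enumerate(centres, start=1):
        r_um = rng.uniform(*nucleus_radius_um)
        r_px = r_um / calibration
        rr, cc = draw.disk((cy, cx), r_px, shape=(h, w))
        hema[rr, cc] = hematoxylin_od
        is_pos = idx in pos_ids
        if is_pos:
            dab[rr, cc] = dab_od
        labels[rr, cc] = idx
        records.append(
            {
                "id": idx,
                "row": cy,
                "col": cx,
                "area_px": int(rr.size),
                "area_um2": rr.size * calibration**2,
                "hematoxylin_od": hematoxylin_od,
                "dab_od": dab_od if is_pos else 0.0,
                "dab_positive": is_pos,
            }
        )

    od_rgb = hema[:, :, None] * m[:, 0] + dab[:, :, None] * m[:, 1]
    pixels = np.clip(np.rint(255.0 * np.power(10.0, -od_rgb)) - 1.0, 0, 255).astype(np.uint8)

    truth = SceneTruth(
        objects=pd.DataFrame(records),
        calibration=calibration,
        seed=seed,
        label_mask=labels,
        meta={"n_positive": n_pos, "od_maps": (hema, dab)},
    )
    return RasterImage(pixels, ("R", "G", "B"), calibration), truth


# --------------------------------------------------------------------------
# fluorescence sections
# --------------------------------------------------------------------------

FLUO_CLASSES = ("KI67+CK20+", "KI67+CK20-", "KI67-CK20+", "KI67-CK20-", "TUNEL+")


def _exact_counts(n: int, fractions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment so planted counts are exact."""
    raw = {k: n * v for k, v in fractions.items()}
    counts = {k: int(np.floor(x)) for k, x in raw.items()}
    short = n - sum(counts.values())
    order = sorted(fractions, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in order[:short]:
        counts[k] += 1
    return counts


def generate_fluorescence_section(
    n_cells: int,
    class_mix: dict[str, float],
    intensity_params: dict | None = None,
    seed: int = 0,
    calibration: float = 0.225,
    nucleus_radius_px: tuple[int, int] = (10, 16),
    ck20_ring_px: int = 8,
    noise_sd: float = 1.0,
) -> tuple[RasterImage, SceneTruth]:
    """Render a multi-channel fluorescence section with planted classes.

    Channels (8-bit, in order): DAPI (nuclear, all cells), KI67
    (nuclear, proliferation-positive classes), CK20 (perinuclear ring,
    differentiation-positive classes), TUNEL (diffuse patch over dying
    cells). Class counts follow ``class_mix`` exactly via largest-
    remainder apportionment; the truth table stores measured per-cell
    channel means and the planted class of every nucleus.
    """
    unknown = set(class_mix) - set(FLUO_CLASSES)
    if unknown:
        raise ValueError(f"unknown classes {sorted(unknown)}; valid: {FLUO_CLASSES}")
    total = sum(class_mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class_mix must sum to 1, got {total}")
    params = {
        "dapi": 160.0,
        "ki67_pos": 120.0,
        "ki67_neg": 5.0,
        "ck20_pos": 200.0,
        "ck20_neg": 3.0,
        "tunel": 150.0,
        "background": 2.0,
    }
    if intensity_params:
        params.update(intensity_params)

    rng = np.random.default_rng(seed)
    counts = _exact_counts(n_cells, {k: class_mix.get(k, 0.0) for k in FLUO_CLASSES})
    class_of = []
    for cls in FLUO_CLASSES:
        class_of.extend([cls] * counts[cls])
    class_of = list(rng.permutation(class_of))

    r_max = nucleus_radius_px[1]
    spacing = 2 * r_max + 2 * ck20_ring_px + 10
    centres, (h, w) = _jittered_grid(n_cells, spacing, jitter=3.0, rng=rng)

    chans = {
        name: np.full((h, w), params["background"], dtype=np.float64)
        for name in ("DAPI", "KI67", "CK20", "TUNEL")
    }
    labels = np.zeros((h, w), dtype=np.int32)
    tunel_mask = np.zeros((h, w), dtype=bool)

    records = []
    for idx, ((cy, cx), cls) in enumerate(zip(centres, class_of), start=1):
        r = rng.integers(nucleus_radius_px[0], nucleus_radius_px[1] + 1)
        rr, cc = draw.disk((cy, cx), r, shape=(h, w))
        labels[rr, cc] = idx
        chans["DAPI"][rr, cc] = params["dapi"]
        ki67_pos = cls.startswith("KI67+")
        ck20_pos = "CK20+" in cls
        chans["KI67"][rr, cc] = params["ki67_pos"] if ki67_pos else params["ki67_neg"]
        ring_rr, ring_cc = draw.disk((cy, cx), r + ck20_ring_px, shape=(h, w))
        ring = np.zeros((h, w), dtype=bool)
        ring[ring_rr, ring_cc] = True
        ring[rr, cc] = False
        chans["CK20"][ring] = params["ck20_pos"] if ck20_pos else params["ck20_neg"]
        if cls == "TUNEL+":
            prr, pcc = draw.disk((cy, cx), r + 5, shape=(h, w))
            chans["TUNEL"][prr, pcc] = params["tunel"]
            tunel_mask[prr, pcc] = True
        records.append(
            {
                "id": idx,
                "row": cy,
                "col": cx,
                "radius_px": int(r),
                "area_px": int(rr.size),
                "area_um2": rr.size * calibration**2,
                "planted_class": cls,
            }
        )

    if noise_sd > 0:
        for name in chans:
            chans[name] = chans[name] + rng.normal(0.0, noise_sd, size=(h, w))
    stack = np.stack(
        [np.clip(np.rint(chans[n]), 0, 255).astype(np.uint8) for n in ("DAPI", "KI67", "CK20", "TUNEL")],
        axis=-1,
    )

    df = pd.DataFrame(records)
    # measured (post-quantization) per-cell channel means, from the truth mask
    for ci, name in enumerate(("DAPI", "KI67", "CK20", "TUNEL")):
        means = []
        for idx in df["id"]:
            means.append(float(stack[:, :, ci][labels == idx].mean()))
        df[f"{name.lower()}_nucleus_mean"] = means

    truth = SceneTruth(
        objects=df,
        calibration=calibration,
        seed=seed,
        label_mask=labels,
        meta={
            "class_counts": counts,
            "tunel_area_um2": float(tunel_mask.sum() * calibration**2),
            "tunel_mask": tunel_mask,
        },
    )
    return RasterImage(stack, ("DAPI", "KI67", "CK20", "TUNEL"), calibration), truth


# --------------------------------------------------------------------------
# chemokine panels
# --------------------------------------------------------------------------


@dataclass
class PanelSimConfig:
    """Generative model for a multiplex chemokine panel.

    The log concentration is additive:
    ``log Value = baseline + condition + oxygen + interaction + donor + noise``
    with a per-donor random intercept (sd ``donor_sd``) and residual sd
    ``residual_sd``, mirroring the mixed model the statistics layer
    fits. Values below ``lower_limit`` are censored to the "OOR <"
    token, as a plate reader below its calibration curve would report.
    """

    n_donors: int = 6
    baseline_log_mean: dict[str, float] = field(default_factory=lambda: {"CXCL8": 5.0})
    condition_effects: dict[str, float] = field(default_factory=dict)
    oxygen_effect: float = 0.0
    interaction_effects: dict[str, float] = field(default_factory=dict)
    donor_sd: float = 0.3
    residual_sd: float = 0.2
    lower_limit: float = 0.0  # pg/mL
    seed: int = 0

    def __post_init__(self):
        if self.donor_sd < 0 or self.residual_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.lower_limit < 0:
            raise ValueError("lower_limit must be >= 0")
        if self.n_donors < 1:
            raise ValueError("need at least one donor")


def simulate_chemokine_panel(config: PanelSimConfig) -> pd.DataFrame:
    """Draw a balanced donor × condition × oxygen panel table.

    Returns a tidy frame with columns donor, oxygen, condition, analyte,
    token — the token is the numeric value as text, or ``"OOR <"`` when
    censored below ``config.lower_limit``.
    """
    rng = np.random.default_rng(config.seed)
    donors = [f"D{i + 1}" for i in range(config.n_donors)]
    rows = []
    for analyte, baseline in config.baseline_log_mean.items():
        intercepts = rng.normal(0.0, config.donor_sd, size=config.n_donors)
        for d_i, donor in enumerate(donors):
            for oxygen in ("2%", "20%"):
                for cond in Condition:
                    log_mu = baseline + config.condition_effects.get(cond.label, 0.0)
                    if oxygen == "20%":
                        log_mu += config.oxygen_effect
                        log_mu += config.interaction_effects.get(cond.label, 0.0)
                    log_val = log_mu + intercepts[d_i] + rng.normal(0.0, config.residual_sd)
                    value = float(np.exp(log_val))
                    token = "OOR <" if value < config.lower_limit else f"{value:.6g}"
                    rows.append(
                        {
                            "donor": donor,
                            "oxygen": oxygen,
                            "condition": cond.label,
                            "analyte": analyte,
                            "token": token,
                        }
                    )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# immunoblot tables
# --------------------------------------------------------------------------


def simulate_blot_table(
    n_donors: int,
    true_fold_changes: dict[str, float],
    noise_sd: float = 0.0,
    seed: int = 0,
    target: str = "LGR5",
    oxygen: str = "2%",
) -> pd.DataFrame:
    """Simulate band intensities with known fold structure over DMSO.

    Per donor, ``target = base × fold(condition) × lognormal noise`` and
    ``gapdh = gapdh_base × lognormal noise``; with ``noise_sd = 0`` the
    normalization pipeline must recover ``true_fold_changes`` exactly.
    Conditions absent from ``true_fold_changes`` get fold 1. DMSO is
    always included as the reference row.
    """
    for cond, fold in true_fold_changes.items():
        if fold <= 0:
            raise ValueError(f"fold change for {cond} must be > 0, got {fold}")
    rng = np.random.default_rng(seed)
    conditions = sorted(
        {Condition.DMSO} | {Condition[c] for c in true_fold_changes}, key=lambda c: c.value
    )
    rows = []
    for i in range(n_donors):
        donor = f"D{i + 1}"
        base = float(np.exp(rng.normal(np.log(1000.0), 0.4)))
        gapdh_base = float(np.exp(rng.normal(np.log(2000.0), 0.4)))
        for cond in conditions:
            fold = true_fold_changes.get(cond.label, 1.0)
            t_noise = np.exp(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 1.0
            g_noise = np.exp(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 1.0
            rows.append(
                {
                    "donor": donor,
                    "oxygen": oxygen,
                    "condition": cond.label,
                    "target": target,
                    "intensity": base * fold * t_noise,
                    "gapdh": gapdh_base * g_noise,
                }
            )
    return pd.DataFrame(rows)
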