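"""Synthetic cohorts with the statistical structure the QC pipeline assumes.

Every generator here is a pure function of its parameters and a seed.
The central object is a :class:`LatentCohort`: each participant carries a
latent quality ``q`` in [0, 1] that drives everything downstream --
expert and community ratings, automated data-quality metrics, phantom
volumes, and tract-profile flattening.  ``q`` correlates with age
(older children move less) and is independent of sex and site by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "METRIC_COLUMNS",
    "INFORMATIVE_METRICS",
    "CONSTANT_METRICS",
    "BUNDLES",
    "LatentCohort",
    "generate_cohort",
    "generate_metrics",
    "simulate_expert_ratings",
    "simulate_community_ratings",
    "generate_volume",
    "generate_bundle_profiles",
    "qc_score_from_quality",
]

#: The 31 automated data-quality metric columns of an ImageQC.csv table,
#: ordered by their global importance in the calibration models.
METRIC_COLUMNS = [
    "raw_neighbor_corr",
    "max_rel_translation",
    "raw_num_bad_slices",
    "t1_neighbor_corr",
    "raw_incoherence_index",
    "raw_coherence_index",
    "max_rel_rotation",
    "mean_fd",
    "max_fd",
    "max_rotation",
    "t1_coherence_index",
    "t1_dice_distance",
    "max_translation",
    "t1_incoherence_index",
    "raw_voxel_size_x",
    "raw_voxel_size_y",
    "raw_voxel_size_z",
    "raw_num_directions",
    "raw_max_b",
    "raw_dimension_y",
    "raw_dimension_z",
    "t1_voxel_size_x",
    "t1_dimension_x",
    "t1_dimension_y",
    "t1_dimension_z",
    "t1_voxel_size_y",
    "t1_voxel_size_z",
    "t1_max_b",
    "t1_num_bad_slices",
    "t1_num_directions",
    "raw_dimension_x",
]

#: Metrics that carry quality information, with the sign of their
#: association with latent quality q (+1 increases with q).
INFORMATIVE_METRICS = {
    "raw_neighbor_corr": +1,
    "max_rel_translation": -1,
    "raw_num_bad_slices": -1,
    "t1_neighbor_corr": +1,
    "raw_incoherence_index": -1,
    "raw_coherence_index": +1,
    "max_rel_rotation": -1,
    "mean_fd": -1,
    "max_fd": -1,
    "max_rotation": -1,
    "t1_coherence_index": +1,
    "t1_dice_distance": -1,
    "max_translation": -1,
    "t1_incoherence_index": -1,
}

#: Acquisition descriptors, constant within site (here: constant across
#: the cohort), mirroring their zero feature importance.
CONSTANT_METRICS = {
    "raw_voxel_size_x": 1.8,
    "raw_voxel_size_y": 1.8,
    "raw_voxel_size_z": 1.8,
    "raw_num_directions": 128.0,
    "raw_max_b": 2000.0,
    "raw_dimension_x": 112.0,
    "raw_dimension_y": 112.0,
    "raw_dimension_z": 72.0,
    "t1_voxel_size_x": 0.8,
    "t1_voxel_size_y": 0.8,
    "t1_voxel_size_z": 0.8,
    "t1_dimension_x": 256.0,
    "t1_dimension_y": 256.0,
    "t1_dimension_z": 224.0,
    "t1_max_b": 0.0,
    "t1_num_bad_slices": 0.0,
    "t1_num_directions": 1.0,
}

#: Twenty-four major white-matter bundles: eight bilateral pairs plus
#: eight callosal segments.
BUNDLES = [
    "IFO_L", "IFO_R",
    "UNC_L", "UNC_R",
    "ATR_L", "ATR_R",
    "CST_L", "CST_R",
    "ARC_L", "ARC_R",
    "SLF_L", "SLF_R",
    "ILF_L", "ILF_R",
    "CGC_L", "CGC_R",
    "Orbital", "AntFrontal", "SupFrontal", "Motor",
    "SupParietal", "Temporal", "PostParietal", "Occipital",
]

DEFAULT_SITES = {"RU": 0.41, "CBIC": 0.42, "CUNY": 0.03, "SI": 0.14}

RATING_LEVELS = (-2, -1, 0, 1, 2)

#: Shared cutpoints mapping latent quality to the 5-level ordinal scale.
EXPERT_CUTPOINTS = (0.2, 0.4, 0.6, 0.8)


@dataclass
class LatentCohort:
    """Per-participant ground truth driving all simulators.

    Attributes
    ----------
    table : pandas.DataFrame
        Columns ``participant_id``, ``site``, ``age``, ``sex``, ``q``
        (latent quality in [0, 1]) and ``true_label``
        (1 iff ``q >= 0.5``).
    """

    table: pd.DataFrame
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def participant_id(self) -> pd.Series:
        return self.table["participant_id"]

    @property
    def q(self) -> np.ndarray:
        return self.table["q"].to_numpy()

    @property
    def true_label(self) -> np.ndarray:
        return self.table["true_label"].to_numpy()


def _participant_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"sub-{i:0{width}d}" for i in range(1, n + 1)]


def generate_cohort(
    n: int,
    site_proportions: dict[str, float] | None = None,
    age_quality_corr: float = 0.31,
    age_range: tuple[float, float] = (5.0, 21.0),
    q_shape: tuple[float, float] = (2.2, 1.3),
    seed: int = 0,
) -> LatentCohort:
    """Draw a cohort with age-linked latent quality.

    Latent quality ``q`` is Beta-distributed with shape ``q_shape``,
    coupled to a uniform age on ``age_range`` through a Gaussian copula
    so that the empirical Pearson correlation of age and ``q``
    approaches ``age_quality_corr`` as ``n`` grows.  Sex and site are
    drawn independently of ``q``.

    Parameters
    ----------
    n : int
        Number of participants (>= 1).
    site_proportions : dict, optional
        Mapping site name -> probability; must sum to 1.  Defaults to a
        four-site layout (RU, CBIC, CUNY, SI) echoing a multi-site
        pediatric study.
    age_quality_corr : float
        Target Pearson correlation between age and ``q``, in (-1, 1).
        The default 0.31 reflects the direct age-quality association
        seen in pediatric imaging (older children move less).
    q_shape : (float, float)
        Beta shape parameters for the marginal of ``q``.  The default
        is mildly pass-skewed; moving it shifts the pass fraction
        monotonically.
    seed : int
        Seed for all randomness.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not -1.0 < age_quality_corr < 1.0:
        raise ValueError("age_quality_corr must lie in (-1, 1)")
    if site_proportions is None:
        site_proportions = dict(DEFAULT_SITES)
    probs = np.asarray(list(site_proportions.values()), dtype=float)
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-8:
        raise ValueError(
            "site_proportions must be nonnegative and sum to 1, got sum "
            f"{probs.sum():.6f}"
        )

    rng = np.random.default_rng(seed)

    # Gaussian copula; for uniform marginals Pearson r maps to a latent
    # normal correlation rho_z = 2 sin(pi r / 6), and the Beta transform
    # attenuates only slightly further.
    rho_z = float(np.clip(2.0 * np.sin(np.pi * age_quality_corr / 6.0), -0.999, 0.999))
    cov = np.array([[1.0, rho_z], [rho_z, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    u_age, u_q = stats.norm.cdf(z[:, 0]), stats.norm.cdf(z[:, 1])

    lo, hi = age_range
    age = lo + (hi - lo) * u_age
    q = stats.beta.ppf(u_q, *q_shape)
    q = np.clip(q, 0.0, 1.0)

    sites = rng.choice(list(site_proportions), size=n, p=probs)
    sex = rng.choice(["male", "female"], size=n)

    table = pd.DataFrame(
        {
            "participant_id": _participant_ids(n),
            "site": sites,
            "age": age,
            "sex": sex,
            "q": q,
            "true_label": (q >= 0.5).astype(int),
        }
    )
    return LatentCohort(
        table=table,
        seed=seed,
        params={
            "n": n,
            "site_proportions": dict(site_proportions),
            "age_quality_corr": age_quality_corr,
            "age_range": tuple(age_range),
            "q_shape": tuple(q_shape),
        },
    )


def generate_metrics(
    cohort: LatentCohort,
    noise_sd: float = 0.9,
    site_shift: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the 31-column automated data-quality metrics table.

    Informative metrics are monotone transforms of latent quality plus
    Gaussian noise, with the sign structure observed empirically:
    neighboring-DWI correlation increases with quality while motion
    summaries (relative translation, outlier-slice counts, framewise
    displacement) decrease with it.  Acquisition descriptors
    (voxel sizes, grid dimensions, direction counts, max b-value) are
    constant.

    Parameters
    ----------
    cohort : LatentCohort
    noise_sd : float
        Noise scale on the standardized latent signal; 0 gives
        deterministic monotone transforms of ``q``.
    site_shift : dict, optional
        Additive shift (in standardized units) applied to the
        informative metrics of all participants of the named sites;
        used to inject controlled site effects for generalization
        experiments.
    seed : int
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be nonempty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")

    rng = np.random.default_rng(seed)
    q = cohort.q
    n = len(cohort)

    shift = np.zeros(n)
    if site_shift:
        site = cohort.table["site"].to_numpy()
        for name, value in site_shift.items():
            shift[site == name] += value

    out = {"participant_id": cohort.participant_id.to_numpy()}

    # Each informative metric sees quality through its own noisy lens.
    scales = {
        "raw_neighbor_corr": (0.60, 0.28),
        "t1_neighbor_corr": (0.55, 0.25),
        "raw_coherence_index": (0.90, 0.45),
        "t1_coherence_index": (0.80, 0.40),
    }
    for name, sign in INFORMATIVE_METRICS.items():
        signal = sign * (q - q.mean()) / max(q.std(), 1e-12)
        noisy = signal + noise_sd * rng.standard_normal(n) + shift
        if name == "raw_num_bad_slices":
            # Count metric: Poisson with rate decreasing in quality.
            lam = np.exp(1.8 + 1.1 * noisy)
            out[name] = rng.poisson(lam).astype(int) if noise_sd > 0 else np.round(lam).astype(int)
        elif name in scales:
            base, spread = scales[name]
            out[name] = base + spread * 0.25 * noisy
        elif name in ("mean_fd", "max_fd", "max_translation",
                      "max_rel_translation", "max_rotation",
                      "max_rel_rotation"):
            # Nonnegative motion summaries, log-linear in the latent.
            out[name] = np.exp(-0.5 + 0.8 * noisy)
        else:
            out[name] = 0.5 + 0.3 * noisy

    for name, value in CONSTANT_METRICS.items():
        out[name] = np.full(n, value)

    table = pd.DataFrame(out)
    return table[["participant_id"] + METRIC_COLUMNS]


def simulate_expert_ratings(
    cohort: LatentCohort,
    n_experts: int = 6,
    bias_sd: float = 0.05,
    noise_sd: float = 0.12,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate ordinal expert ratings on the 5-level QC scale.

    Each expert thresholds ``q + bias_e + noise`` at shared cutpoints
    (0.2, 0.4, 0.6, 0.8) onto {-2, -1, 0, 1, 2}.  Expert-specific bias
    is drawn once per expert; view-to-view noise is i.i.d.  The default
    noise calibration places mean pairwise quadratic-weighted kappa in
    the 0.5-0.8 regime typical of expert dMRI QC panels.

    Returns a wide DataFrame indexed by participant_id with one column
    per expert (``expert_01`` ...).
    """
    if n_experts < 2:
        raise ValueError("n_experts must be >= 2")
    if bias_sd < 0 or noise_sd < 0:
        raise ValueError("bias_sd and noise_sd must be nonnegative")

    rng = np.random.default_rng(seed)
    q = cohort.q
    biases = bias_sd * rng.standard_normal(n_experts)
    cutpoints = np.asarray(EXPERT_CUTPOINTS)

    data = {}
    for e in range(n_experts):
        latent = q + biases[e] + noise_sd * rng.standard_normal(len(cohort))
        data[f"expert_{e + 1:02d}"] = np.searchsorted(cutpoints, latent, side="left") - 2
    out = pd.DataFrame(data, index=pd.Index(cohort.participant_id, name="participant_id"))
    return out


def simulate_community_ratings(
    cohort: LatentCohort,
    n_raters: int = 20,
    views_per_participant: int = 10,
    reliability_distribution: tuple[float, float] = (3.5, 1.5),
    sensitivity_distribution: tuple[float, float] = (12.0, 1.5),
    optimism: float = 0.4,
    rater_coverage: float = 1.0,
    rater_quality: tuple[np.ndarray, np.ndarray] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate long-form binary pass/fail community ratings.

    Each rater draws a specificity (probability of failing a truly bad
    scan) from ``reliability_distribution`` and a sensitivity from
    ``sensitivity_distribution``.  Sensitivities are anchored high and
    specificities are lower and widely spread: community raters see
    only slice subsets, so they rarely fail a clean scan but often
    miss artifacts -- which is also why their ratings are less
    conservative than expert ratings.  ``optimism`` additionally mixes
    every rater's pass probability toward 1.  Views are slice subsets
    of the same volume; view effects are i.i.d.

    With defaults (20 raters x 10 views, full coverage) each
    participant accrues ~200 ratings, the density regime of a
    community-science deployment.

    Parameters
    ----------
    rater_quality : (sens, spec) arrays, optional
        Explicit per-rater sensitivity/specificity, overriding the
        distributional draw (e.g. an oracle rater with both equal 1).

    Returns
    -------
    pandas.DataFrame
        Long form with columns ``participant_id``, ``rater_id``,
        ``view``, ``rating`` (0/1).
    """
    if n_raters < 1:
        raise ValueError("n_raters must be >= 1")
    if views_per_participant < 1:
        raise ValueError("views_per_participant must be >= 1")
    if optimism < 0:
        raise ValueError("optimism must be >= 0")
    if not 0 < rater_coverage <= 1:
        raise ValueError("rater_coverage must be in (0, 1]")

    rng = np.random.default_rng(seed)
    if rater_quality is not None:
        sens = np.asarray(rater_quality[0], dtype=float)
        spec = np.asarray(rater_quality[1], dtype=float)
        if sens.shape != (n_raters,) or spec.shape != (n_raters,):
            raise ValueError("rater_quality arrays must have length n_raters")
    else:
        sens = rng.beta(*sensitivity_distribution, size=n_raters)
        spec = rng.beta(*reliability_distribution, size=n_raters)

    labels = cohort.true_label
    n = len(cohort)
    pids = cohort.participant_id.to_numpy()

    frames = []
    for r in range(n_raters):
        # Sparse random assignment of participants to this rater.
        mask = rng.random(n) < rater_coverage
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        p_pass = np.where(labels[idx] == 1, sens[r], 1.0 - spec[r])
        p_pass = p_pass + optimism * (1.0 - p_pass)
        views = np.repeat(np.arange(views_per_participant), idx.size)
        part = np.tile(idx, views_per_participant)
        p_rep = np.tile(p_pass, views_per_participant)
        rating = (rng.random(part.size) < p_rep).astype(int)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": pids[part],
                    "rater_id": f"rater_{r + 1:03d}",
                    "view": views,
                    "rating": rating,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["participant_id", "rater_id", "view"]).reset_index(drop=True)


def _head_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Smooth ellipsoidal head-like intensity profile in [0, 1]."""
    zz, yy, xx = np.meshgrid(
        *[np.linspace(-1.0, 1.0, s) for s in shape], indexing="ij"
    )
    r2 = (xx / 0.78) ** 2 + (yy / 0.85) ** 2 + (zz / 0.80) ** 2
    return np.exp(-2.2 * np.maximum(r2 - 0.25, 0.0))


def _tube_mask(shape, axis: int, center: tuple[float, float], radius: float) -> np.ndarray:
    """Boolean mask of a tube running the full extent along ``axis``.

    ``center`` gives the tube center in normalized [-1, 1] coordinates
    of the two transverse axes (in increasing axis order).
    """
    coords = np.meshgrid(*[np.linspace(-1.0, 1.0, s) for s in shape], indexing="ij")
    transverse = [coords[ax] for ax in range(3) if ax != axis]
    d2 = (transverse[0] - center[0]) ** 2 + (transverse[1] - center[1]) ** 2
    return d2 < radius**2


def generate_volume(
    q: float,
    shape: tuple[int, int, int] = (32, 32, 32),
    banding_depth: float = 0.4,
    seed: int = 0,
) -> np.ndarray:
    """Generate a 4-channel QC phantom volume.

    Channels are ``(b0, decfa_x, decfa_y, decfa_z)`` stacked on the
    first axis; spatial axes are ordered (z, y, x) with z the
    inferior-superior axis.  A clean (high-``q``) phantom contains a
    smooth head-like b=0 blob plus three tube-shaped bundles whose
    DEC-FA energy concentrates in the channel matching their
    orientation.  As ``q`` drops, an alternating-slice gain (banding, a
    motion artifact signature) modulates b0 along z and the DEC-FA
    channels are attenuated and blurred; severity scales with
    ``(1 - q) * banding_depth``.

    Returns
    -------
    numpy.ndarray
        Array of shape ``(4, *shape)``, all channels finite and
        nonnegative, DEC-FA channels in [0, 1].
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must lie in [0, 1], got {q}")
    shape = tuple(int(s) for s in shape)
    if any(s < 16 for s in shape):
        raise ValueError("each extent must be >= 16")

    rng = np.random.default_rng(seed)
    severity = (1.0 - q) * banding_depth

    b0 = 0.25 + 0.75 * _head_mask(shape)

    # Axes: 0=z (superior-inferior), 1=y (anterior-posterior),
    # 2=x (lateral).  decfa channel index 0=x, 1=y, 2=z.
    decfa = np.zeros((3,) + shape)
    tubes = [
        (2, (0.35, 0.0), 0),   # lateral tube -> x channel
        (1, (-0.30, 0.0), 1),  # anterior-posterior tube -> y channel
        (0, (0.0, -0.35), 2),  # superior-inferior tube -> z channel
    ]
    for axis, center, channel in tubes:
        mask = _tube_mask(shape, axis, center, radius=0.22)
        decfa[channel][mask] = 0.75
        for other in range(3):
            if other != channel:
                decfa[other][mask] = 0.08

    # Degradation: attenuate and blur directional contrast.
    decfa *= 1.0 - 1.3 * severity
    if severity > 0:
        decfa = np.stack(
            [ndimage.gaussian_filter(c, sigma=2.5 * severity) for c in decfa]
        )

    # Banding: alternating-slice gain along the inferior-superior axis.
    gain = 1.0 - severity * 0.5 * (1.0 - np.cos(np.pi * np.arange(shape[0])))
    b0 = b0 * gain[:, None, None]

    vol = np.concatenate([b0[None], decfa], axis=0)
    vol += 0.01 * rng.standard_normal(vol.shape)
    vol = np.clip(vol, 0.0, None)
    vol[1:] = np.clip(vol[1:], 0.0, 1.0)
    return vol


def banding_index(volume: np.ndarray) -> float:
    """Relative even/odd alternation of axial slice means of b0.

    Near 0 for a clean volume; grows with banding severity.
    """
    b0 = volume[0]
    slice_means = b0.mean(axis=(1, 2))
    even, odd = slice_means[::2].mean(), slice_means[1::2].mean()
    return float(abs(even - odd) / slice_means.mean())


def _bundle_template(bundle: str, metric: str, n_nodes: int = 100) -> np.ndarray:
    """Deterministic per-bundle template: base level + 1-3 Gaussian bumps.

    Templates are fixed properties of the bundle (seeded by a stable
    hash of its name), not of the user-facing seed.
    """
    key = sum((i + 1) * ord(c) for i, c in enumerate(bundle + metric)) % (2**31)
    rng = np.random.default_rng(key)
    x = np.linspace(0.0, 1.0, n_nodes)
    if metric == "FA":
        base, amp = 0.45, 0.14
    else:  # MD in um^2/ms
        base, amp = 0.75, 0.10
    template = np.full(n_nodes, base)
    for _ in range(rng.integers(1, 4)):
        center = rng.uniform(0.15, 0.85)
        width = rng.uniform(0.05, 0.2)
        sign = rng.choice([-1.0, 1.0])
        template += sign * amp * rng.uniform(0.5, 1.0) * np.exp(
            -((x - center) ** 2) / (2 * width**2)
        )
    return template


def generate_bundle_profiles(
    cohort: LatentCohort,
    site_effects: dict[str, tuple[float, float]] | None = None,
    missing_rate: float = 0.05,
    noise_sd: float = 0.02,
    flatten_strength: float = 0.9,
    age_effect: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate tract profiles (24 bundles x {FA, MD} x 100 nodes).

    Per (bundle, metric) a fixed node-wise template is modulated by a
    logarithmic age trajectory acting on the *shape* of the profile
    (bump amplitudes grow for FA and shrink for MD with log-age),
    additive/multiplicative site effects, and observation noise.  Low
    quality flattens the profile: each participant-bundle profile is
    shrunk toward its own mean by ``flatten_strength * (1 - q)``, so
    low-``q`` participants lose the age-informative shape -- the
    mechanism by which QC screening improves downstream age prediction.

    Parameters
    ----------
    site_effects : dict, optional
        Mapping site -> (additive offset, multiplicative scale).
    missing_rate : float in [0, 1)
        Fraction of (participant, bundle) pairs dropped entirely, to
        exercise imputation.
    flatten_strength : float
        0 disables QC-dependent flattening (negative control).
    age_effect : float
        0 disables the age trend.

    Returns
    -------
    pandas.DataFrame
        Long form with columns ``participant_id``, ``bundle``,
        ``metric``, ``node``, ``value``.  A complete participant
        contributes exactly 24 x 2 x 100 = 4,800 values.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")

    rng = np.random.default_rng(seed)
    if site_effects is None:
        site_effects = {}

    n_nodes = 100
    q = cohort.q
    age = cohort.table["age"].to_numpy()
    sites = cohort.table["site"].to_numpy()
    pids = cohort.participant_id.to_numpy()
    log_age_c = np.log(age) - np.log(13.0)

    records = []
    for bundle in BUNDLES:
        # Independent missingness per (participant, bundle).
        drop = rng.random(len(cohort)) < missing_rate
        for metric in ("FA", "MD"):
            template = _bundle_template(bundle, metric, n_nodes)
            mean_level = template.mean()
            shape = template - mean_level
            # Age scales the profile shape: FA bumps deepen with age,
            # MD bumps flatten (maturation trajectories are logarithmic).
            direction = 1.0 if metric == "FA" else -1.0
            age_scale = 1.0 + direction * age_effect * log_age_c
            profiles = mean_level + age_scale[:, None] * shape[None, :]

            # QC-dependent flattening toward each profile's own mean.
            w = np.clip(flatten_strength * (1.0 - q), 0.0, 1.0)
            prof_mean = profiles.mean(axis=1, keepdims=True)
            profiles = prof_mean + (1.0 - w[:, None]) * (profiles - prof_mean)

            for name, (offset, scale) in site_effects.items():
                at_site = sites == name
                profiles[at_site] = profiles[at_site] * scale + offset

            if noise_sd > 0:
                profiles = profiles + noise_sd * rng.standard_normal(profiles.shape)

            keep = ~drop
            n_keep = int(keep.sum())
            records.append(
                pd.DataFrame(
                    {
                        "participant_id": np.repeat(pids[keep], n_nodes),
                        "bundle": bundle,
                        "metric": metric,
                        "node": np.tile(np.arange(n_nodes), n_keep),
                        "value": profiles[keep].ravel(),
                    }
                )
            )
    return pd.concat(records, ignore_index=True)


def qc_score_from_quality(
    q: np.ndarray,
    sharpness: float = 3.0,
    noise_sd: float = 0.25,
    ceiling: float = 0.955,
    seed: int = 0,
) -> np.ndarray:
    """Emulate a calibrated classifier's QC probability from latent quality.

    Classifier probabilities are more extreme than the latent quality
    itself (confident passes near 1, confident fails near 0), but a
    voting ensemble's averaged probability rarely reaches complete
    certainty.  This helper sharpens ``q`` on the logit scale, adds
    logit noise, and rescales by ``ceiling``, producing the bimodal,
    top-compressed score distribution on which QC-cutoff sweeps
    operate: a visible fraction of clear failures below the lowest
    cutoff and a thin tail above the highest.
    """
    rng = np.random.default_rng(seed)
    q = np.clip(np.asarray(q, dtype=float), 1e-6, 1 - 1e-6)
    logits = sharpness * np.log(q / (1 - q))
    if noise_sd > 0:
        logits = logits + noise_sd * rng.standard_normal(q.shape)
    return ceiling / (1.0 + np.exp(-logits))
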