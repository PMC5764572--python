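"""Monte-Carlo model of the two-color co-localization measurement.

The simulator reproduces the measurement chain on a synthetic detector
field: kinetochores sit on a rectangular pixel grid (default 0-280 px in x
and 0-180 px in y at 10 px spacing, 29 x 19 = 551 positions).  At each
position the green centroid is drawn at the origin with per-axis centroid
noise (CDsd x standard normal), and the red centroid carries the true
separation S along the (rotated) x axis, an optional axial offset, a
chromatic-aberration displacement, and its own centroid noise.  The CA at
each position is either the field mean plus CAsd x standard normal
(``ca_mode="random"``) or a linear field gradient with matching mean and SD
(``ca_mode="gradient"``).  The corrected displacement subtracts the mean CA
exactly as in the experimental analysis, and all downstream statistics —
S(2D), S(3D), ML2D/ML3D, angles alpha and beta — are computed with the same
code paths used for real centroid tables.

Optional ``ksd`` adds kinetochore-to-kinetochore variability: a Gaussian
spread of the true separation itself, distinct from measurement noise.

The simulated Delta is the corrected x component Sx of each kinetochore
(the grid model has no sister pairs); its SD is sqrt(2) x CDsd_x when CAsd
is zero, which is what the CDsd inversion in :func:`infer_cdsd` exploits.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ml_distance import ml_fit
from .separation_analysis import SeparationSummary, summarize, separation_record

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "simulate_field",
    "sweep_separations",
    "sweep_nuisance",
    "infer_cdsd",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Field model parameters; defaults are the reference measurement regime.

    Noise defaults: centroid determination CDsd = (4, 4, 8) nm, chromatic
    aberration mean (13.1, 15.8, 3.5) nm with CAsd = (9.1, 7.5, 17.6) nm.
    """

    S: float = 60.0  # true separation, nm
    alpha_true: float = 0.0  # in-plane rotation of the true offset, degrees
    beta_true: float = 0.0  # out-of-plane elevation, degrees
    cdsd: tuple[float, float, float] = (4.0, 4.0, 8.0)  # nm
    ca_mean: tuple[float, float, float] = (13.1, 15.8, 3.5)  # nm
    ca_sd: tuple[float, float, float] = (9.1, 7.5, 17.6)  # nm
    z_offset: float = 0.0  # nm
    ksd: float = 0.0  # kinetochore-to-kinetochore variability, nm
    ksd_mode: str = "magnitude"  # or "vector"
    ca_mode: str = "random"  # or "gradient"
    x_max_px: int = 280
    y_max_px: int = 180
    spacing_px: int = 10
    px_nm: float = 64.0
    n_reps: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.x_max_px % self.spacing_px or self.y_max_px % self.spacing_px:
            raise ValueError("spacing_px must divide x_max_px and y_max_px")
        if any(s < 0 for s in self.cdsd + self.ca_sd) or self.ksd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.ca_mode not in ("random", "gradient"):
            raise ValueError(f"unknown ca_mode {self.ca_mode!r}")
        if self.ksd_mode not in ("magnitude", "vector"):
            raise ValueError(f"unknown ksd_mode {self.ksd_mode!r}")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return (self.x_max_px // self.spacing_px + 1, self.y_max_px // self.spacing_px + 1)

    @property
    def n_positions(self) -> int:
        nx, ny = self.grid_shape
        return nx * ny

    def grid_positions_px(self) -> np.ndarray:
        """(n, 2) array of kinetochore field positions in pixels."""
        xs = np.arange(0, self.x_max_px + 1, self.spacing_px)
        ys = np.arange(0, self.y_max_px + 1, self.spacing_px)
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel()]).astype(float)

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        for k in ("cdsd", "ca_mean", "ca_sd"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class SimulationResult:
    """Per-kinetochore records plus pooled and per-seed summaries."""

    config: SimulationConfig
    records: pd.DataFrame  # one row per kinetochore per rep
    summary: SeparationSummary  # pooled over all reps
    rep_summaries: list[SeparationSummary] = field(default_factory=list)

    def rep_means(self) -> pd.DataFrame:
        """One row per rep with the headline statistics."""
        rows = []
        for i, s in enumerate(self.rep_summaries):
            rows.append(
                dict(
                    rep=i,
                    s2d_mean=s.s2d_mean,
                    s2d_sd=s.s2d_sd,
                    s3d_mean=s.s3d_mean,
                    s3d_sd=s.s3d_sd,
                    ml2d_mu=s.ml2d.mu_hat if s.ml2d else np.nan,
                    ml3d_mu=s.ml3d.mu_hat if s.ml3d else np.nan,
                    ml3d_at_boundary=bool(s.ml3d.at_boundary) if s.ml3d else False,
                    alpha_mean=s.alpha_mean,
                    alpha_sd=s.alpha_sd,
                    beta_mean=s.beta_mean,
                    beta_sd=s.beta_sd,
                    z_offset=s.z_offset,
                    zs3d_mean=s.zs3d_mean,
                    delta_mean=s.delta_mean,
                    delta_sd=s.delta_sd,
                )
            )
        return pd.DataFrame(rows)


def _gradient_ca(config: SimulationConfig, pos_px: np.ndarray, rng: np.random.Generator):
    """Per-position CA from linear field gradients with matching mean and SD.

    Lateral CA drifts roughly linearly across the detector (about -30 nm
    over 280 px in x and -21 nm over 180 px in y); the slopes are chosen at
    that scale, intercepts center the field mean on ``ca_mean``, and
    residual Gaussian scatter tops the per-axis variance up to ``ca_sd``.
    Axial CA has no gradient.
    """
    n = pos_px.shape[0]
    slopes = np.array([-30.0 / config.x_max_px, -21.0 / config.y_max_px, 0.0])
    coords = np.column_stack([pos_px[:, 0], pos_px[:, 1], np.zeros(n)])
    ca = np.empty((n, 3))
    for ax in range(3):
        trend = slopes[ax] * coords[:, ax]
        trend_var = trend.var()
        resid_var = max(config.ca_sd[ax] ** 2 - trend_var, 0.0)
        intercept = config.ca_mean[ax] - trend.mean()
        ca[:, ax] = intercept + trend + np.sqrt(resid_var) * rng.standard_normal(n)
    return ca


def _simulate_one_rep(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    pos = config.grid_positions_px()
    n = pos.shape[0]
    cdsd = np.asarray(config.cdsd, dtype=float)
    ca_mean = np.asarray(config.ca_mean, dtype=float)
    ca_sd = np.asarray(config.ca_sd, dtype=float)

    green = cdsd * rng.standard_normal((n, 3))

    a = np.radians(config.alpha_true)
    b = np.radians(config.beta_true)
    direction = np.array([np.cos(b) * np.cos(a), np.cos(b) * np.sin(a), np.sin(b)])
    if config.ksd > 0 and config.ksd_mode == "magnitude":
        magnitudes = config.S + config.ksd * rng.standard_normal(n)
        offset = magnitudes[:, None] * direction[None, :]
    else:
        offset = np.broadcast_to(config.S * direction, (n, 3)).copy()
        if config.ksd > 0:
            offset = offset + config.ksd * rng.standard_normal((n, 3))

    # The correction subtracts the field-mean CA from each displacement, so
    # only the deviation ca_p - ca_mean survives; generating the deviation
    # directly keeps the mean-CA cancellation exact to the last bit.
    if config.ca_mode == "random":
        ca_dev = ca_sd * rng.standard_normal((n, 3))
    else:
        ca_dev = _gradient_ca(config, pos, rng) - ca_mean

    red_noise = cdsd * rng.standard_normal((n, 3))
    corrected = offset + ca_dev + np.array([0.0, 0.0, config.z_offset]) + red_noise - green

    df = pd.DataFrame(corrected, columns=["Sx", "Sy", "Sz"])
    df.insert(0, "x_px", pos[:, 0])
    df.insert(1, "y_px", pos[:, 1])
    return df


def _records_from_vectors(df: pd.DataFrame) -> list:
    return [
        separation_record(sx, sy, sz)
        for sx, sy, sz in zip(df["Sx"].values, df["Sy"].values, df["Sz"].values)
    ]


def simulate_field(config: SimulationConfig) -> SimulationResult:
    """Run the field simulation for ``config.n_reps`` independent seeds.

    The K-K axis of the simulated field is the x axis, so the per-position
    Delta analogue is the corrected x component Sx.  Identical configs give
    bit-identical results.
    """
    rng = np.random.default_rng(config.seed)
    frames = []
    rep_summaries = []
    for rep in range(config.n_reps):
        df = _simulate_one_rep(config, rng)
        records = _records_from_vectors(df)
        for col, attr in (
            ("s2d", "s2d"),
            ("s3d", "s3d"),
            ("alpha", "alpha"),
            ("beta", "beta"),
        ):
            df[col] = [getattr(r, attr) for r in records]
        df["delta"] = df["Sx"]
        df.insert(0, "rep", rep)
        frames.append(df)
        rep_summaries.append(summarize(records, delta_values=df["delta"].tolist()))
    all_df = pd.concat(frames, ignore_index=True)
    pooled = summarize(
        _records_from_vectors(all_df), delta_values=all_df["delta"].tolist()
    )
    return SimulationResult(
        config=config, records=all_df, summary=pooled, rep_summaries=rep_summaries
    )


def _mean_over_reps(result: SimulationResult) -> dict:
    """Average the per-rep headline statistics (each rep is one experiment)."""
    rm = result.rep_means()
    out = {
        "s2d_mean": rm["s2d_mean"].mean(),
        "s2d_sd": rm["s2d_sd"].mean(),
        "s3d_mean": rm["s3d_mean"].mean(),
        "s3d_sd": rm["s3d_sd"].mean(),
        "ml2d_mu": rm["ml2d_mu"].mean(),
        "ml3d_mu": rm["ml3d_mu"].mean(),
        "ml3d_mu_median": rm["ml3d_mu"].median(),
        "ml3d_boundary_frac": rm["ml3d_at_boundary"].mean(),
        "alpha_mean": rm["alpha_mean"].mean(),
        "alpha_sd": rm["alpha_sd"].mean(),
        "beta_mean": rm["beta_mean"].mean(),
        "beta_sd": rm["beta_sd"].mean(),
        "z_offset": rm["z_offset"].mean(),
        "zs3d_mean": rm["zs3d_mean"].mean(),
        "delta_mean": rm["delta_mean"].mean(),
        "delta_sd": rm["delta_sd"].mean(),
    }
    return {k: float(v) for k, v in out.items()}


def sweep_separations(config: SimulationConfig, S_values) -> pd.DataFrame:
    """One summary row per true separation S, averaged over the config's reps."""
    if len(S_values) == 0:
        raise ValueError("S_values must be non-empty")
    rows = []
    for s in S_values:
        result = simulate_field(config.replace(S=float(s)))
        row = {"S": float(s)}
        row.update(_mean_over_reps(result))
        rows.append(row)
    return pd.DataFrame(rows)


def sweep_nuisance(config: SimulationConfig, parameter: str, values) -> pd.DataFrame:
    """Sweep one nuisance parameter; one averaged summary row per value.

    ``parameter`` is one of ``"CAsd_scale"`` (multiplies all three CA SDs),
    ``"z_offset"`` (nm) or ``"Ksd"`` (nm).
    """
    if len(values) == 0:
        raise ValueError("values must be non-empty")
    rows = []
    for v in values:
        if parameter == "CAsd_scale":
            cfg = config.replace(ca_sd=tuple(float(v) * s for s in config.ca_sd))
        elif parameter == "z_offset":
            cfg = config.replace(z_offset=float(v))
        elif parameter == "Ksd":
            cfg = config.replace(ksd=float(v))
        else:
            raise ValueError(f"unknown nuisance parameter {parameter!r}")
        result = simulate_field(cfg)
        row = {parameter: float(v)}
        row.update(_mean_over_reps(result))
        rows.append(row)
    return pd.DataFrame(rows)


def infer_cdsd(
    target_delta_sd: float,
    S: float,
    config: SimulationConfig | None = None,
    tol: float = 0.02,
    max_iter: int = 60,
) -> tuple[tuple[float, float, float], float]:
    """Invert the simulation for the centroid noise implied by a Delta SD.

    With CAsd forced to zero and the axial constraint CDsd_z = 2 CDsd_xy
    (axial resolution is about half the lateral), bisect on CDsd_xy until
    the simulated Delta SD matches ``target_delta_sd``.  Each bisection
    probe reuses the same seed so the objective is a deterministic,
    monotone function of CDsd_xy (Delta = Sx implies Delta SD =
    sqrt(2) CDsd_x exactly in distribution).

    Returns ``((cdsd_x, cdsd_y, cdsd_z), achieved_delta_sd)``.
    """
    if target_delta_sd <= 0:
        raise ValueError("target_delta_sd must be > 0")
    base = (config or SimulationConfig()).replace(
        S=float(S), ca_sd=(0.0, 0.0, 0.0), n_reps=max((config or SimulationConfig()).n_reps, 5)
    )

    def delta_sd(c: float) -> float:
        # Delta in the grid model is the corrected Sx, so only the vector
        # draws are needed; skip the ML summaries for speed.
        cfg = base.replace(cdsd=(c, c, 2 * c))
        rng = np.random.default_rng(cfg.seed)
        sds = [
            float(_simulate_one_rep(cfg, rng)["Sx"].std(ddof=1)) for _ in range(cfg.n_reps)
        ]
        return float(np.mean(sds))

    lo, hi = 1e-3, 100.0
    if not (delta_sd(lo) <= target_delta_sd <= delta_sd(hi)):
        raise ValueError(
            f"target Delta SD {target_delta_sd} nm unreachable for CDsd_xy in [{lo}, {hi}] nm"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        v = delta_sd(mid)
        if abs(v - target_delta_sd) < tol:
            lo = hi = mid
            break
        if v < target_delta_sd:
            lo = mid
        else:
            hi = mid
    c = 0.5 * (lo + hi)
    return (c, c, 2 * c), delta_sd(c)
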