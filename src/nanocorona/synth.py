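"""Ground-truthed synthetic two-channel SMLM localization scenes.

Scenes emulate internalized nanomaterial agglomerates carrying fluorescently
labelled protein coronas: each agglomerate is a ball (or a two-channel
core--shell object) populated by fluorophores, each fluorophore blinks a
geometric number of times, every blink is jittered by the localization
precision and assigned a random acquisition frame, and a homogeneous Poisson
background of unbound labels covers the field.  Pure-background scenes stand
in for the no-nanomaterial serum controls.

Channel ``ch1`` plays the role of the initial (FITC-labelled) corona and
``ch2`` the exchanged (Alexa-647-labelled) population; in shell mode ``ch1``
is confined to the tightly bound core and ``ch2`` to the looser secondary
layer.

Agglomerate diameters are lognormal, parameterized by the *arithmetic* mean
and standard deviation so that the per-coating presets (mean ± sd of the
internalized agglomerate size) can be used directly; the lognormal guarantees
positive diameters even at the large coefficient of variation of the
uncoated and AA4040 coatings.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import LocalizationTable, write_localizations

__all__ = [
    "ShellGeometry",
    "CoronaSceneConfig",
    "Agglomerate",
    "GroundTruth",
    "SMLM_SIZE_PRESETS",
    "scene_preset",
    "sample_agglomerates",
    "emit_localizations",
    "shell_scene",
    "generate_scene",
    "write_scene",
    "lognormal_params",
]

#: Noise / background sentinel used in ground-truth cluster ids.
NOISE = -1

#: Per-coating internalized agglomerate size presets, nm (mean, sd).
SMLM_SIZE_PRESETS: dict[str, tuple[float, float]] = {
    "TiO2-un": (765.5, 258.2),
    "TiO2-F127": (1494.0, 282.2),
    "TiO2-PVP": (354.0, 66.48),
    "TiO2-AA4040": (6676.0, 2819.0),
}


@dataclass(frozen=True)
class ShellGeometry:
    """Two-channel core--shell geometry of a corona object.

    The tightly bound initial corona occupies the core ball
    (``core_diameter``); the exchanged secondary layer occupies the spherical
    shell between ``core_diameter`` and ``outer_diameter``.  Defaults follow
    the observed ~350 nm core inside a ~600 nm object.
    """

    core_diameter: float = 350.0
    outer_diameter: float = 600.0

    def __post_init__(self) -> None:
        if not (0 < self.core_diameter < self.outer_diameter):
            raise ConfigurationError(
                "shell requires 0 < core_diameter < outer_diameter, got "
                f"{self.core_diameter} / {self.outer_diameter}"
            )


@dataclass(frozen=True)
class CoronaSceneConfig:
    """Generative parameters of a synthetic SMLM scene.

    Parameters
    ----------
    field_size
        Field extent in nm, ``(x, y)`` for 2D or ``(x, y, z)`` for 3D.
    n_agglomerates
        Number of nanomaterial agglomerate clusters.
    diameter_mean, diameter_sd
        Arithmetic mean and sd (nm) of the lognormal agglomerate diameter.
    shell
        ``None`` for uniform-ball clusters, or a :class:`ShellGeometry` to
        confine channel 1 to the core and channel 2 to the secondary layer.
    channel_fractions
        Per-cluster fraction of channel-1 fluorophores in [0, 1]; a scalar
        applies to every cluster, a sequence is cycled over clusters.
    fluorophores_per_cluster
        Labelled protein molecules per agglomerate.
    mean_blinks
        Expected localizations per fluorophore (geometric law, minimum 1).
    localization_precision
        ``(sigma_xy, sigma_z)`` Gaussian jitter in nm.
    background_rate
        Diffuse background localizations per µm² (per µm³ in 3D).
    n_frames
        Acquisition length; frames are assigned uniformly.
    min_separation
        Optional minimum centre-to-centre distance (nm) between clusters, for
        scenes that must be well separated; ``None`` places centres freely.
    seed
        Default seed used when no generator is passed explicitly.
    """

    field_size: tuple[float, ...] = (20_000.0, 20_000.0)
    n_agglomerates: int = 5
    diameter_mean: float = 354.0
    diameter_sd: float = 66.48
    shell: ShellGeometry | None = None
    channel_fractions: float | Sequence[float] = 1.0
    fluorophores_per_cluster: int = 100
    mean_blinks: float = 5.0
    localization_precision: tuple[float, float] = (20.0, 50.0)
    background_rate: float = 0.5
    n_frames: int = 20_000
    min_separation: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.field_size) not in (2, 3):
            raise ConfigurationError("field_size must have 2 or 3 components")
        if any(not (s > 0) for s in self.field_size):
            raise ConfigurationError("field_size components must be positive")
        if self.n_agglomerates < 0:
            raise ConfigurationError("n_agglomerates must be >= 0")
        if not (self.diameter_mean > 0 and self.diameter_sd >= 0):
            raise ConfigurationError("diameter moments must be positive")
        for f in np.atleast_1d(np.asarray(self.channel_fractions, dtype=float)):
            if not (0.0 <= f <= 1.0):
                raise ConfigurationError(f"channel fraction {f} outside [0, 1]")
        if self.fluorophores_per_cluster < 0:
            raise ConfigurationError("fluorophores_per_cluster must be >= 0")
        if not (self.mean_blinks >= 1):
            raise ConfigurationError("mean_blinks must be >= 1")
        if any(s < 0 for s in self.localization_precision):
            raise ConfigurationError("localization precision must be >= 0")
        if self.background_rate < 0:
            raise ConfigurationError("background_rate must be >= 0")
        if self.n_frames < 1:
            raise ConfigurationError("n_frames must be >= 1")

    @property
    def ndim(self) -> int:
        return len(self.field_size)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.shell is not None:
            d["shell"] = dataclasses.asdict(self.shell)
        d["channel_fractions"] = (
            float(self.channel_fractions)
            if np.isscalar(self.channel_fractions)
            else [float(f) for f in self.channel_fractions]
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CoronaSceneConfig":
        d = dict(d)
        if d.get("shell") is not None and not isinstance(d["shell"], ShellGeometry):
            d["shell"] = ShellGeometry(**d["shell"])
        if "field_size" in d:
            d["field_size"] = tuple(d["field_size"])
        if "localization_precision" in d:
            d["localization_precision"] = tuple(d["localization_precision"])
        return cls(**d)


def scene_preset(name: str, **overrides) -> CoronaSceneConfig:
    """Scene configuration carrying a named coating's size preset."""
    try:
        mean, sd = SMLM_SIZE_PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {sorted(SMLM_SIZE_PRESETS)}"
        ) from None
    return CoronaSceneConfig(diameter_mean=mean, diameter_sd=sd, **overrides)


@dataclass(frozen=True)
class Agglomerate:
    """One planted cluster: centre (nm), diameter (nm), channel-1 fraction."""

    center: tuple[float, ...]
    diameter: float
    channel1_fraction: float


@dataclass
class GroundTruth:
    """Per-localization and per-cluster generative truth.

    ``true_cluster`` holds one integer per localization (−1 for background),
    ``channel`` the emitting channel id; ``clusters`` has one row per planted
    agglomerate with its centre, diameter and *empirical* channel-1 fraction
    of its fluorophores.
    """

    true_cluster: np.ndarray
    channel: np.ndarray
    clusters: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "loc_index": np.arange(len(self.true_cluster)),
                "true_cluster": self.true_cluster,
                "channel": self.channel,
            }
        )


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with arithmetic mean/sd as given.

    ``sigma² = ln(1 + (sd/mean)²)``, ``mu = ln(mean) − sigma²/2``.
    A zero sd degenerates to a point mass at ``mean``.
    """
    if sd == 0:
        return float(np.log(mean)), 0.0
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(mu), float(np.sqrt(sigma2))


def _cluster_fractions(config: CoronaSceneConfig) -> np.ndarray:
    fr = np.atleast_1d(np.asarray(config.channel_fractions, dtype=float))
    reps = int(np.ceil(config.n_agglomerates / max(len(fr), 1)))
    return np.tile(fr, reps)[: config.n_agglomerates]


def sample_agglomerates(
    config: CoronaSceneConfig, rng: np.random.Generator
) -> list[Agglomerate]:
    """Draw agglomerate centres, diameters and channel compositions.

    Centres are uniform over the region where the whole object (its drawn
    diameter, or the shell outer diameter in shell mode) fits inside the
    field; diameters are lognormal with the configured arithmetic moments;
    the channel-1 fraction follows ``channel_fractions`` cycled per cluster.

    Raises
    ------
    ConfigurationError
        If the field cannot contain a drawn object; the message names the
        offending diameter.
    """
    if config.n_agglomerates == 0:
        return []
    mu, sigma = lognormal_params(config.diameter_mean, config.diameter_sd)
    diameters = (
        np.full(config.n_agglomerates, config.diameter_mean)
        if sigma == 0.0
        else rng.lognormal(mu, sigma, size=config.n_agglomerates)
    )
    fractions = _cluster_fractions(config)
    field = np.asarray(config.field_size, dtype=float)
    out: list[Agglomerate] = []
    centers: list[np.ndarray] = []
    for diameter, fraction in zip(diameters, fractions):
        extent = config.shell.outer_diameter if config.shell is not None else diameter
        radius = extent / 2.0
        if np.any(field < extent):
            raise ConfigurationError(
                f"field {tuple(field)} nm too small for an object of diameter "
                f"{extent:.1f} nm (drawn agglomerate diameter {diameter:.1f} nm)"
            )
        for _ in range(10_000):
            center = radius + rng.random(len(field)) * (field - 2 * radius)
            if config.min_separation is None or all(
                np.linalg.norm(center - c) >= config.min_separation for c in centers
            ):
                break
        else:
            raise ConfigurationError(
                "could not place a cluster at min_separation "
                f"{config.min_separation} nm in field {tuple(field)} nm"
            )
        centers.append(center)
        out.append(Agglomerate(tuple(center), float(diameter), float(fraction)))
    return out


def _uniform_ball(rng: np.random.Generator, n: int, radius: float, d: int) -> np.ndarray:
    """n points uniform in a d-ball (radius via the r^d inverse CDF)."""
    direction = rng.standard_normal((n, d))
    direction /= np.maximum(np.linalg.norm(direction, axis=1, keepdims=True), 1e-300)
    r = radius * rng.random(n) ** (1.0 / d)
    return direction * r[:, None]


def _uniform_shell(
    rng: np.random.Generator, n: int, r_inner: float, r_outer: float, d: int
) -> np.ndarray:
    direction = rng.standard_normal((n, d))
    direction /= np.maximum(np.linalg.norm(direction, axis=1, keepdims=True), 1e-300)
    u = rng.random(n)
    r = (r_inner**d + u * (r_outer**d - r_inner**d)) ** (1.0 / d)
    return direction * r[:, None]


def emit_localizations(
    clusters: Sequence[Agglomerate],
    config: CoronaSceneConfig,
    rng: np.random.Generator,
) -> tuple[LocalizationTable, GroundTruth]:
    """Blink the scene's fluorophores and add Poisson background.

    Each fluorophore sits uniformly in its cluster's ball (core or secondary
    layer per channel in shell mode), emits ``Geometric(1/mean_blinks)``
    localizations (support starts at 1), each jittered by the isotropic
    Gaussian precision and stamped with a uniform frame in
    ``[1, n_frames]``.  Background localizations form a homogeneous Poisson
    process over the field with ground-truth id −1 and a fair coin channel.
    """
    d = config.ndim
    sigma = np.array(
        [config.localization_precision[0]] * 2
        + ([config.localization_precision[1]] if d == 3 else [])
    )
    p_blink = 1.0 / config.mean_blinks

    xs: list[np.ndarray] = []
    truth_cluster: list[np.ndarray] = []
    truth_channel: list[np.ndarray] = []
    cluster_rows = []
    for ci, agg in enumerate(clusters):
        nf = config.fluorophores_per_cluster
        is_ch1 = rng.random(nf) < agg.channel1_fraction
        center = np.asarray(agg.center)
        pos = np.empty((nf, d))
        if config.shell is None:
            pos[:] = center + _uniform_ball(rng, nf, agg.diameter / 2.0, d)
        else:
            core_r = config.shell.core_diameter / 2.0
            outer_r = config.shell.outer_diameter / 2.0
            n1 = int(is_ch1.sum())
            pos[is_ch1] = center + _uniform_ball(rng, n1, core_r, d)
            pos[~is_ch1] = center + _uniform_shell(rng, nf - n1, core_r, outer_r, d)
        blinks = rng.geometric(p_blink, size=nf)
        rep = np.repeat(np.arange(nf), blinks)
        emitted = pos[rep] + rng.standard_normal((rep.size, d)) * sigma
        xs.append(emitted)
        truth_cluster.append(np.full(rep.size, ci))
        truth_channel.append(np.where(is_ch1[rep], "ch1", "ch2"))
        cluster_rows.append(
            {
                "cluster": ci,
                **{f"center_{ax}": c for ax, c in zip("xyz", agg.center)},
                "diameter": agg.diameter,
                "channel1_fraction": float(is_ch1.mean()) if nf else float("nan"),
            }
        )

    field = np.asarray(config.field_size, dtype=float)
    measure_um = float(np.prod(field / 1000.0))  # µm² or µm³
    n_bg = int(rng.poisson(config.background_rate * measure_um))
    if n_bg:
        bg = rng.random((n_bg, d)) * field
        xs.append(bg)
        truth_cluster.append(np.full(n_bg, NOISE))
        truth_channel.append(np.where(rng.random(n_bg) < 0.5, "ch1", "ch2"))

    if xs:
        coords = np.concatenate(xs, axis=0)
        cluster_ids = np.concatenate(truth_cluster)
        channels = np.concatenate(truth_channel)
    else:
        coords = np.empty((0, d))
        cluster_ids = np.empty(0, dtype=int)
        channels = np.empty(0, dtype=object)

    n = coords.shape[0]
    table = LocalizationTable.from_arrays(
        x=coords[:, 0],
        y=coords[:, 1],
        z=coords[:, 2] if d == 3 else None,
        frame=rng.integers(1, config.n_frames + 1, size=n),
        photons=rng.exponential(1000.0, size=n),
        channel=channels,
    )
    truth = GroundTruth(
        true_cluster=cluster_ids.astype(int),
        channel=np.asarray(channels, dtype=object),
        clusters=pd.DataFrame(cluster_rows),
    )
    return table, truth


def generate_scene(
    config: CoronaSceneConfig, rng: np.random.Generator | None = None
) -> tuple[LocalizationTable, GroundTruth]:
    """Sample agglomerates and emit the full scene in one step."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    clusters = sample_agglomerates(config, rng)
    return emit_localizations(clusters, config, rng)


def shell_scene(
    config: CoronaSceneConfig, rng: np.random.Generator | None = None
) -> tuple[LocalizationTable, GroundTruth]:
    """Core--shell two-channel scene (channel 1 core, channel 2 layer).

    Raises
    ------
    ConfigurationError
        If ``config.shell`` is unset.
    """
    if config.shell is None:
        raise ConfigurationError("shell_scene requires a shell geometry in the config")
    return generate_scene(config, rng)


def write_scene(
    table: LocalizationTable,
    truth: GroundTruth,
    config: CoronaSceneConfig,
    out_dir: str | Path,
) -> dict[str, str]:
    """Write localization CSV, ground-truth sidecar CSV and JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "localizations": str(out / "localizations.csv"),
        "ground_truth": str(out / "ground_truth.csv"),
        "clusters": str(out / "clusters.json"),
    }
    write_localizations(table, paths["localizations"])
    truth.to_frame().to_csv(paths["ground_truth"], index=False)
    manifest = {
        "config": config.to_dict(),
        "n_localizations": len(table),
        "clusters": truth.clusters.to_dict(orient="records"),
    }
    with open(paths["clusters"], "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return paths
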