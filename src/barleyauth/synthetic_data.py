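"""Seeded generators for all four input modalities of the harvest-year study.

The generators emulate, at the processed-data level, the measurements of a
two-cultivar (Quench, Steffi) x two-year (2017 wet, 2018 hot/dry) spring
barley sample set:

* FT-NIR diffuse-reflectance spectra of whole kernels on the instrument grid
  12,500 -> 3,600 cm^-1 at 16 cm^-1 steps, in triplicate per sample: a smooth
  convex baseline plus six Gaussian absorbance bands (lipid 8264 and 5665,
  moisture 6800 and 5170, starch 6300, protein 4854 cm^-1) whose amplitudes
  carry the harvest-year effect (2018: lipid and protein bands up, moisture
  and starch bands down), plus i.i.d. detector noise per replicate.
* Per-sample isotope triplets (d13C, d15N, d18O, per-mil) drawn normally
  around the per-group location defaults.
* The 1H-NMR betaine region as a Lorentzian singlet at 3.255 ppm with a
  year-dependent amplitude and small chemical-shift jitter.
* Daily weather (precipitation, mean and maximum temperature) whose annual
  and June-August totals are enforced exactly by post-hoc rescaling and
  whose hot-day count (tmax > 25 C in June-August) is calibrated exactly.

Within-class NIR variability is a two-dimensional bounded sample state drawn
uniformly from a disc: one mode along the harvest-year band signature
(samples differ in individual drought exposure) and one orthogonal
compositional mode on the same bands.  Replicates share their sample's band
amplitudes and differ only in detector noise.

Identical (seed, config) pairs reproduce bit-identical output; every
generator derives its random stream from the seed plus a fixed per-modality
tag, so the modalities are independent and insensitive to call order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .isotope_stats import IsotopeRecord
from .nmr_marker import NmrSpectrum
from .spectra_prep import Spectrum

__all__ = [
    "BandParam",
    "BetaineParams",
    "WeatherYearParams",
    "GeneratorConfig",
    "gen_nir_spectra",
    "gen_isotopes",
    "gen_nmr_region",
    "gen_weather",
    "write_dataset",
    "NIR_GRID",
]

CULTIVARS = ("Quench", "Steffi")
YEARS = (2017, 2018)

#: FT-NIR acquisition grid: 12,500 down to 3,604 cm^-1 in 16 cm^-1 steps.
NIR_GRID = 12500.0 - 16.0 * np.arange(557)

_STREAM_NIR, _STREAM_ISO, _STREAM_NMR, _STREAM_WX = 11, 13, 17, 19


@dataclass(frozen=True)
class BandParam:
    """One NIR absorbance band: Gaussian center and width (cm^-1) and the
    per-year amplitude (absorbance units)."""

    center: float
    width: float
    amplitude_by_year: dict[int, float]


@dataclass(frozen=True)
class BetaineParams:
    """Betaine singlet parameters: per-year (mean, sd) amplitude, chemical
    shift jitter sd (ppm), additive noise sd, Lorentzian half-width (ppm)."""

    amplitude_by_year: dict[int, tuple[float, float]]
    shift_jitter_sd: float = 0.001
    noise_sd: float = 0.01
    halfwidth: float = 0.0015


@dataclass(frozen=True)
class WeatherYearParams:
    """Targets for one calendar year of daily weather."""

    annual_precip: float
    summer_precip: float
    annual_tmean: float
    hot_days: int
    seasonal_amplitude: float = 9.0
    tmean_noise_sd: float = 2.0


def _default_bands() -> list[BandParam]:
    # 2018 direction: lipid (8264, 5665) and protein (4854) up,
    # moisture (6800, 5170) and starch (6300) down.
    spec = [
        (8264.0, 60.0, 0.45, +0.06),
        (6800.0, 80.0, 0.60, -0.08),
        (6300.0, 70.0, 0.50, -0.04),
        (5665.0, 60.0, 0.55, +0.05),
        (5170.0, 70.0, 0.70, -0.07),
        (4854.0, 55.0, 0.65, +0.05),
    ]
    return [
        BandParam(c, w, {2017: a, 2018: a + d}) for c, w, a, d in spec
    ]


def _default_isotopes() -> dict[tuple[str, int], dict[str, tuple[float, float]]]:
    # Locations are the printed per-group medians; spreads are calibrated so
    # the Quench d13C groups fully separate, Steffi d13C separates weakly
    # (significant but not a top-ranked variable), and Steffi d15N/d18O
    # overlap heavily.
    return {
        ("Quench", 2017): {"d13C": (-27.1, 0.3), "d15N": (3.0, 0.45), "d18O": (29.6, 0.5)},
        ("Quench", 2018): {"d13C": (-25.2, 0.3), "d15N": (5.0, 0.45), "d18O": (28.2, 0.5)},
        ("Steffi", 2017): {"d13C": (-26.7, 0.45), "d15N": (4.5, 0.5), "d18O": (26.9, 0.6)},
        ("Steffi", 2018): {"d13C": (-26.0, 0.45), "d15N": (4.7, 0.5), "d18O": (26.8, 0.6)},
    }


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_per_group: dict[tuple[str, int], int] = field(
        default_factory=lambda: {
            ("Quench", 2017): 19,
            ("Quench", 2018): 20,
            ("Steffi", 2017): 22,
            ("Steffi", 2018): 25,
        }
    )
    band_params: list[BandParam] = field(default_factory=_default_bands)
    isotope_params: dict[tuple[str, int], dict[str, tuple[float, float]]] = field(
        default_factory=_default_isotopes
    )
    betaine_params: BetaineParams = field(
        default_factory=lambda: BetaineParams(
            amplitude_by_year={2017: (0.55, 0.05), 2018: (1.00, 0.06)}
        )
    )
    weather_params: dict[int, WeatherYearParams] = field(
        default_factory=lambda: {
            2017: WeatherYearParams(573.9, 285.1, 9.8, 28),
            2018: WeatherYearParams(377.1, 77.0, 10.9, 48),
        }
    )
    noise_sd_nir: float = 0.002
    #: Disc radii (absorbance units) of the two bounded within-class NIR
    #: sample-state modes: along the year signature and orthogonal to it.
    sample_state_scale: tuple[float, float] = (0.06, 0.06)
    #: Bound (cm^-1) of the uniform per-sample, per-band center jitter that
    #: emulates moisture/temperature-driven band-position variation.
    band_center_jitter: float = 3.0
    n_replicates: int = 3

    def __post_init__(self):
        for key, n in self.n_per_group.items():
            if n <= 0:
                raise ValueError(f"group count for {key} must be positive")
        for b in self.band_params:
            if not (3600.0 <= b.center <= 12500.0):
                raise ValueError(f"band center {b.center} outside 12,500-3,600 cm^-1")
            if b.width <= 0:
                raise ValueError("band width must be positive")
        for key, per_el in self.isotope_params.items():
            for el, (_, sd) in per_el.items():
                if sd < 0:
                    raise ValueError(f"negative sd for {key}/{el}")
        for y, (_, sd) in self.betaine_params.amplitude_by_year.items():
            if sd < 0:
                raise ValueError(f"negative betaine amplitude sd for {y}")
        if self.betaine_params.shift_jitter_sd < 0 or self.betaine_params.noise_sd < 0:
            raise ValueError("betaine jitter/noise sd must be non-negative")
        for y, wp in self.weather_params.items():
            if wp.annual_precip < 0 or wp.summer_precip < 0:
                raise ValueError(f"negative precipitation target for {y}")
            if wp.summer_precip > wp.annual_precip:
                raise ValueError(f"summer precipitation exceeds annual total for {y}")
            if not (0 <= wp.hot_days <= 92):
                raise ValueError(f"hot-day count for {y} must be within 0..92")
        if self.noise_sd_nir < 0:
            raise ValueError("noise_sd_nir must be non-negative")
        if any(s < 0 for s in self.sample_state_scale):
            raise ValueError("sample_state_scale entries must be non-negative")
        if self.band_center_jitter < 0:
            raise ValueError("band_center_jitter must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")

    def group_count(self, cultivar: str, year: int) -> int:
        try:
            return self.n_per_group[(cultivar, year)]
        except KeyError:
            raise KeyError(
                f"no group ({cultivar!r}, {year}) in configuration"
            ) from None

    def sample_ids(self, cultivar: str, year: int) -> list[str]:
        n = self.group_count(cultivar, year)
        return [f"{cultivar}-{year}-{i + 1:02d}" for i in range(n)]


def _rng(config: GeneratorConfig, stream: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream, *extra])


def _state_directions(config: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Unit vectors (in band-amplitude space) of the two sample-state modes."""
    delta = np.array(
        [b.amplitude_by_year[2018] - b.amplitude_by_year[2017] for b in config.band_params]
    )
    norm = np.linalg.norm(delta)
    if norm == 0:
        z = np.zeros_like(delta)
        return z, z
    d_unit = delta / norm
    signs = np.where(np.arange(delta.size) % 2 == 0, 1.0, -1.0)
    h = signs * np.abs(delta)
    h = h - (h @ d_unit) * d_unit
    h_norm = np.linalg.norm(h)
    h_unit = h / h_norm if h_norm > 0 else np.zeros_like(h)
    return d_unit, h_unit


def _disc_points(rng: np.random.Generator, n: int) -> np.ndarray:
    """n points uniform on the closed unit disc."""
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    r = np.sqrt(rng.uniform(0.0, 1.0, n))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _nir_baseline(x: np.ndarray) -> np.ndarray:
    # Smooth convex background, removable by rubber-band correction.
    t = (x - 3600.0) / 8900.0
    return 0.15 + 0.10 * (1.0 - t) ** 2 + 0.02 * t


def gen_nir_spectra(
    config: GeneratorConfig, cultivar: str, year: int
) -> list[list[Spectrum]]:
    """Triplicate FT-NIR spectra for every sample of one (cultivar, year)
    group; outer list indexes samples, inner list the replicates."""
    if cultivar not in CULTIVARS:
        raise KeyError(f"unknown cultivar {cultivar!r}")
    n = config.group_count(cultivar, year)
    rng = _rng(config, _STREAM_NIR, CULTIVARS.index(cultivar), year)
    x = NIR_GRID
    baseline = _nir_baseline(x)
    centers = np.array([b.center for b in config.band_params])
    widths = np.array([b.width for b in config.band_params])
    base_amps = np.array([b.amplitude_by_year[year] for b in config.band_params])
    d_unit, h_unit = _state_directions(config)
    s1, s2 = config.sample_state_scale
    states = _disc_points(rng, n)
    cj = config.band_center_jitter
    shifts = rng.uniform(-cj, cj, size=(n, centers.size)) if cj > 0 else np.zeros((n, centers.size))
    out: list[list[Spectrum]] = []
    for i in range(n):
        amps = base_amps + states[i, 0] * s1 * d_unit + states[i, 1] * s2 * h_unit
        c_i = centers + shifts[i]
        profiles = np.exp(
            -((x[None, :] - c_i[:, None]) ** 2) / (2.0 * widths[:, None] ** 2)
        )
        signal = baseline + amps @ profiles
        reps = []
        for _ in range(config.n_replicates):
            noise = rng.normal(0.0, config.noise_sd_nir, x.size)
            reps.append(Spectrum(x.copy(), signal + noise))
        out.append(reps)
    return out


def gen_isotopes(config: GeneratorConfig) -> list[IsotopeRecord]:
    """Per-sample isotope triplets for every configured group."""
    records: list[IsotopeRecord] = []
    for (cultivar, year), per_el in sorted(config.isotope_params.items()):
        if (cultivar, year) not in config.n_per_group:
            raise KeyError(f"isotope_params group ({cultivar!r}, {year}) has no count")
        n = config.group_count(cultivar, year)
        rng = _rng(config, _STREAM_ISO, CULTIVARS.index(cultivar), year)
        draws = {
            el: rng.normal(mean, sd, n) for el, (mean, sd) in sorted(per_el.items())
        }
        for i, sid in enumerate(config.sample_ids(cultivar, year)):
            records.append(
                IsotopeRecord(
                    sample_id=sid,
                    cultivar=cultivar,
                    year=year,
                    d13C=float(draws["d13C"][i]),
                    d15N=float(draws["d15N"][i]),
                    d18O=float(draws["d18O"][i]),
                )
            )
    return records


#: 1H-NMR ppm grid for the betaine region, descending 3.300 -> 3.210 ppm.
NMR_GRID = 3.300 - 0.0004 * np.arange(226)

BETAINE_CENTER = 3.255


def gen_nmr_region(
    config: GeneratorConfig, cultivar: str, year: int
) -> list[NmrSpectrum]:
    """One betaine-region spectrum per sample of a (cultivar, year) group:
    Lorentzian singlet at 3.255 ppm with per-sample amplitude and small
    chemical-shift jitter, plus additive noise."""
    if cultivar not in CULTIVARS:
        raise KeyError(f"unknown cultivar {cultivar!r}")
    n = config.group_count(cultivar, year)
    bp = config.betaine_params
    if year not in bp.amplitude_by_year:
        raise KeyError(f"no betaine amplitude configured for year {year}")
    mean_amp, sd_amp = bp.amplitude_by_year[year]
    rng = _rng(config, _STREAM_NMR, CULTIVARS.index(cultivar), year)
    ppm = NMR_GRID
    out: list[NmrSpectrum] = []
    for _ in range(n):
        amp = max(rng.normal(mean_amp, sd_amp), 0.0)
        shift = rng.normal(0.0, bp.shift_jitter_sd)
        center = BETAINE_CENTER + shift
        g2 = bp.halfwidth**2
        signal = amp * g2 / ((ppm - center) ** 2 + g2)
        noise = rng.normal(0.0, bp.noise_sd, ppm.size)
        out.append(NmrSpectrum(ppm.copy(), signal + noise))
    return out


def gen_weather(config: GeneratorConfig, year: int) -> pd.DataFrame:
    """365 daily records (date, precip_mm, tmean_C, tmax_C) for one year.

    Daily precipitation is gamma-distributed with dry days, then the
    June-August block and the remainder of the year are rescaled so the
    summer and annual totals match the configured targets exactly.  The
    temperature series is a seasonal sinusoid plus noise, shifted so the
    June-August count of days with tmax > 25 C equals the configured number
    and the annual mean temperature matches the target.
    """
    if year not in config.weather_params:
        raise KeyError(f"no weather parameters for year {year}")
    wp = config.weather_params[year]
    rng = _rng(config, _STREAM_WX, year)
    dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    ndays = len(dates)
    jja = np.asarray(np.isin(dates.month, [6, 7, 8]))

    wet = rng.uniform(size=ndays) < 0.45
    raw = np.where(wet, rng.gamma(shape=0.7, scale=4.0, size=ndays), 0.0)
    precip = np.zeros(ndays)
    for mask, target in ((jja, wp.summer_precip), (~jja, wp.annual_precip - wp.summer_precip)):
        block = raw[mask]
        total = block.sum()
        if target == 0:
            precip[mask] = 0.0
        elif total == 0:
            precip[mask] = target / mask.sum()
        else:
            precip[mask] = block * (target / total)

    doy = np.arange(1, ndays + 1)
    tmean = (
        wp.annual_tmean
        + wp.seasonal_amplitude * np.cos(2.0 * np.pi * (doy - 202) / 365.0)
        + rng.normal(0.0, wp.tmean_noise_sd, ndays)
    )
    spread = 5.0 + np.abs(rng.normal(0.0, 1.5, ndays))
    tmax = tmean + spread

    v = np.sort(tmax[jja])[::-1]
    k = wp.hot_days
    if k == 0:
        delta = 25.0 - v[0] - 0.5
    elif k == v.size:
        delta = 25.0 - v[-1] + 0.5
    else:
        delta = 25.0 - 0.5 * (v[k - 1] + v[k])
    tmax += delta
    tmean += delta
    tmean += wp.annual_tmean - tmean.mean()
    tmax = np.maximum(tmax, tmean)

    return pd.DataFrame(
        {
            "date": dates.strftime("%Y-%m-%d"),
            "precip_mm": precip,
            "tmean_C": tmean,
            "tmax_C": tmax,
        }
    )


def write_dataset(config: GeneratorConfig, outdir) -> None:
    """Write the full synthetic dataset to ``outdir``: isotope and weather
    CSVs, per-replicate NIR and per-sample NMR two-column text files with
    manifest CSVs, and the generator configuration as JSON."""
    from pathlib import Path

    from .isotope_stats import records_to_frame
    from .spectra_prep import write_spectrum

    out = Path(outdir)
    (out / "nir").mkdir(parents=True, exist_ok=True)
    (out / "nmr").mkdir(parents=True, exist_ok=True)

    records_to_frame(gen_isotopes(config)).to_csv(out / "isotopes.csv", index=False)
    for year in sorted(config.weather_params):
        gen_weather(config, year).to_csv(out / f"weather_{year}.csv", index=False)

    nir_rows, nmr_rows = [], []
    groups = sorted({k for k in config.n_per_group})
    for cultivar, year in groups:
        ids = config.sample_ids(cultivar, year)
        for sid, reps in zip(ids, gen_nir_spectra(config, cultivar, year)):
            for j, spec in enumerate(reps, start=1):
                rel = f"nir/{sid}_rep{j}.txt"
                write_spectrum(out / rel, spec)
                nir_rows.append(
                    {"sample_id": sid, "cultivar": cultivar, "year": year,
                     "replicate": j, "path": rel}
                )
        for sid, spec in zip(ids, gen_nmr_region(config, cultivar, year)):
            rel = f"nmr/{sid}.txt"
            np.savetxt(
                out / rel,
                np.column_stack([spec.ppm, spec.intensity]),
                header="ppm intensity",
                fmt="%.8g",
            )
            nmr_rows.append(
                {"sample_id": sid, "cultivar": cultivar, "year": year, "path": rel}
            )
    pd.DataFrame(nir_rows).to_csv(out / "nir_manifest.csv", index=False)
    pd.DataFrame(nmr_rows).to_csv(out / "nmr_manifest.csv", index=False)

    with open(out / "config.json", "w") as fh:
        json.dump(config_to_dict(config), fh, indent=2)


def config_to_dict(config: GeneratorConfig) -> dict:
    """JSON-serializable form of a generator configuration (tuple keys are
    flattened to 'cultivar:year' strings)."""
    d = asdict(config)
    d["n_per_group"] = {f"{c}:{y}": n for (c, y), n in config.n_per_group.items()}
    d["isotope_params"] = {
        f"{c}:{y}": per_el for (c, y), per_el in config.isotope_params.items()
    }
    d["weather_params"] = {str(y): asdict(wp) for y, wp in config.weather_params.items()}
    d["betaine_params"] = asdict(config.betaine_params)
    d["betaine_params"]["amplitude_by_year"] = {
        str(y): list(v) for y, v in config.betaine_params.amplitude_by_year.items()
    }
    for b in d["band_params"]:
        b["amplitude_by_year"] = {str(y): a for y, a in b["amplitude_by_year"].items()}
    return d


def config_from_dict(d: dict) -> GeneratorConfig:
    def _key(s: str) -> tuple[str, int]:
        c, y = s.split(":")
        return c, int(y)

    bands = [
        BandParam(
            center=b["center"],
            width=b["width"],
            amplitude_by_year={int(y): a for y, a in b["amplitude_by_year"].items()},
        )
        for b in d.get("band_params", [])
    ] or _default_bands()
    bp = d.get("betaine_params")
    betaine = (
        BetaineParams(
            amplitude_by_year={int(y): tuple(v) for y, v in bp["amplitude_by_year"].items()},
            shift_jitter_sd=bp.get("shift_jitter_sd", 0.001),
            noise_sd=bp.get("noise_sd", 0.01),
            halfwidth=bp.get("halfwidth", 0.0015),
        )
        if bp
        else BetaineParams(amplitude_by_year={2017: (0.55, 0.05), 2018: (1.00, 0.06)})
    )
    weather = {
        int(y): WeatherYearParams(**wp) for y, wp in d.get("weather_params", {}).items()
    } or {
        2017: WeatherYearParams(573.9, 285.1, 9.8, 28),
        2018: WeatherYearParams(377.1, 77.0, 10.9, 48),
    }
    iso = {
        _key(k): {el: tuple(v) for el, v in per_el.items()}
        for k, per_el in d.get("isotope_params", {}).items()
    } or _default_isotopes()
    return GeneratorConfig(
        seed=d.get("seed", 0),
        n_per_group={_key(k): n for k, n in d["n_per_group"].items()}
        if "n_per_group" in d
        else GeneratorConfig().n_per_group,
        band_params=bands,
        isotope_params=iso,
        betaine_params=betaine,
        weather_params=weather,
        noise_sd_nir=d.get("noise_sd_nir", 0.002),
        sample_state_scale=tuple(d.get("sample_state_scale", (0.06, 0.06))),
        band_center_jitter=d.get("band_center_jitter", 3.0),
        n_replicates=d.get("n_replicates", 3),
    )
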