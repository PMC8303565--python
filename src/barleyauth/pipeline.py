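"""End-to-end orchestration: from synthetic generation (or input files)
through preprocessing, fusion, statistics, classification, cross-validation,
NMR marker comparison and climate indices to one structured report.

The report is a plain nested dict (JSON-serializable, no timestamps) so a
run is fully regenerable from (config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import climate_index as ci
from . import fusion_chemometrics as fc
from . import isotope_stats as iso
from . import nmr_marker as nm
from . import spectra_prep as sp
from . import synthetic_data as sd

__all__ = [
    "RunConfig",
    "run",
    "prepare_sample",
    "variable_importance_report",
    "BAND_CENTERS",
    "REFERENCE_PRECIP_ANNUAL",
    "REFERENCE_PRECIP_SUMMER",
]

#: The six harvest-year-sensitive NIR band centers (cm^-1): lipid 8264/5665,
#: moisture 6800/5170, starch 6300, protein 4854.
BAND_CENTERS = (8264.0, 6800.0, 6300.0, 5665.0, 5170.0, 4854.0)

#: 30-year (1981-2010) reference-period precipitation means for the sampling
#: region, derived from reported (total, percent-of-reference) pairs for the
#: 2017 season (573.9 mm = 106% annual; 285.1 mm = 155% June-August).  These
#: are derived constants, not station measurements.
REFERENCE_PRECIP_ANNUAL = ci.derive_reference(573.9, 106.0)
REFERENCE_PRECIP_SUMMER = ci.derive_reference(285.1, 155.0)


@dataclass(frozen=True)
class RunConfig:
    mode: str = "synthetic"  # "synthetic" | "files"
    seed: int = 0
    input_dir: str | None = None  # files mode: directory with manifests/CSVs
    cultivars: tuple[str, ...] = ("Quench", "Steffi")
    bins: int = 300
    top_k: int = 50
    alpha: float = 0.05
    n_components: int = 2
    n_iter: int = 100
    train_fraction: float = 0.9
    average_replicates: bool = True
    betaine_mode: str = "height"
    generator: sd.GeneratorConfig | None = None

    def __post_init__(self):
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "files" and not self.input_dir:
            raise ValueError("files mode requires input_dir")
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.top_k <= 0 or self.bins <= 0 or self.n_iter <= 0:
            raise ValueError("bins, top_k and n_iter must be positive")

    def generator_config(self) -> sd.GeneratorConfig:
        if self.generator is not None:
            return self.generator
        return sd.GeneratorConfig(seed=self.seed)


def prepare_sample(replicates: list[sp.Spectrum], n_bins: int = 300) -> sp.BinnedSpectrum:
    """Preprocess one sample's replicate spectra: rubber-band baseline per
    replicate, restriction to 4,000-11,000 cm^-1, replicate averaging, then
    binning."""
    corrected = [
        sp.restrict_range(sp.rubberband_baseline(r)) for r in replicates
    ]
    return sp.bin_spectrum(sp.average_replicates(corrected), n_bins=n_bins)


def _load_inputs(config: RunConfig):
    """Return (nir: {cultivar: {sample_id: [replicates]}}, isotopes,
    nmr: {cultivar: {year: [spectra]}}, weather: {year: DataFrame})."""
    if config.mode == "synthetic":
        gen = config.generator_config()
        nir: dict[str, dict[str, list[sp.Spectrum]]] = {}
        nmr: dict[str, dict[int, list[nm.NmrSpectrum]]] = {}
        for cultivar in config.cultivars:
            nir[cultivar] = {}
            nmr[cultivar] = {}
            for year in (2017, 2018):
                ids = gen.sample_ids(cultivar, year)
                for sid, reps in zip(ids, sd.gen_nir_spectra(gen, cultivar, year)):
                    nir[cultivar][sid] = reps
                nmr[cultivar][year] = sd.gen_nmr_region(gen, cultivar, year)
        isotopes = sd.gen_isotopes(gen)
        weather = {y: sd.gen_weather(gen, y) for y in sorted(gen.weather_params)}
        return nir, isotopes, nmr, weather

    root = Path(config.input_dir)
    for required in ("isotopes.csv", "nir_manifest.csv", "nmr_manifest.csv"):
        if not (root / required).exists():
            raise FileNotFoundError(f"missing input file: {root / required}")
    isotopes = iso.frame_to_records(pd.read_csv(root / "isotopes.csv"))
    nir_manifest = pd.read_csv(root / "nir_manifest.csv")
    nir = {c: {} for c in config.cultivars}
    for row in nir_manifest.itertuples(index=False):
        if row.cultivar not in nir:
            continue
        path = root / row.path
        if not path.exists():
            raise FileNotFoundError(f"missing spectrum file: {path}")
        nir[row.cultivar].setdefault(row.sample_id, []).append(sp.read_spectrum(path))
    nmr_manifest = pd.read_csv(root / "nmr_manifest.csv")
    nmr = {c: {2017: [], 2018: []} for c in config.cultivars}
    for row in nmr_manifest.itertuples(index=False):
        if row.cultivar not in nmr:
            continue
        path = root / row.path
        if not path.exists():
            raise FileNotFoundError(f"missing spectrum file: {path}")
        data = np.loadtxt(path, comments="#", ndmin=2)
        nmr[row.cultivar][int(row.year)].append(nm.NmrSpectrum(data[:, 0], data[:, 1]))
    weather = {}
    for f in sorted(root.glob("weather_*.csv")):
        year = int(f.stem.split("_")[1])
        weather[year] = pd.read_csv(f)
    return nir, isotopes, nmr, weather


def _test_result_dict(t: iso.TestResult) -> dict:
    return {
        "U": t.U,
        "p": t.p,
        "median_2017": t.median_a,
        "median_2018": t.median_b,
        "n_2017": t.n_a,
        "n_2018": t.n_b,
        "method": t.method,
        "significant": t.significant,
    }


def run(config: RunConfig, out_dir: str | None = None) -> dict:
    """Execute the full analysis and return the report dict.

    Stages: load/generate -> NIR preprocessing -> fusion -> isotope
    statistics -> chemometric fit and Monte Carlo CV -> betaine comparison
    -> aridity summary.  With ``out_dir`` the report JSON and tabular CSV
    artifacts are also written.
    """
    stage = "load"
    try:
        nir, isotopes, nmr, weather = _load_inputs(config)

        report: dict = {
            "provenance": {
                "seed": config.seed,
                "mode": config.mode,
                "config_hash": _config_hash(config),
                "parameters": {
                    "bins": config.bins,
                    "top_k": config.top_k,
                    "alpha": config.alpha,
                    "n_components": config.n_components,
                    "n_iter": config.n_iter,
                    "train_fraction": config.train_fraction,
                },
            },
            "cultivars": {},
            "climate": {},
        }

        for cultivar in config.cultivars:
            stage = f"spectra_prep[{cultivar}]"
            binned: dict[str, sp.BinnedSpectrum] = {}
            for sid, reps in nir[cultivar].items():
                if config.average_replicates:
                    binned[sid] = prepare_sample(reps, n_bins=config.bins)
                else:
                    for j, r in enumerate(reps, start=1):
                        binned[f"{sid}#r{j}"] = prepare_sample([r], n_bins=config.bins)

            stage = f"fuse[{cultivar}]"
            recs = [r for r in isotopes if r.cultivar == cultivar]
            if not config.average_replicates:
                recs = [
                    iso.IsotopeRecord(f"{r.sample_id}#r{j}", r.cultivar, r.year,
                                      r.d13C, r.d15N, r.d18O)
                    for r in recs
                    for j in range(1, len(nir[cultivar][r.sample_id]) + 1)
                ]
            table = fc.fuse(binned, recs, cultivar=cultivar)

            stage = f"isotope_stats[{cultivar}]"
            iso_stats = {
                el: _test_result_dict(
                    iso.group_summary(isotopes, cultivar, el).test
                )
                for el in iso.ELEMENTS
            }

            stage = f"chemometrics[{cultivar}]"
            fitted = fc.fit_pipeline(
                table, k=config.top_k, n_components=config.n_components,
                alpha=config.alpha,
            )
            pred = fitted.predict(table)
            full_acc = fc.accuracy(pred, table.labels)
            cv = fc.monte_carlo_cv(
                table,
                n_iter=config.n_iter,
                train_fraction=config.train_fraction,
                k=config.top_k,
                seed=config.seed,
                n_components=config.n_components,
                alpha=config.alpha,
            )

            stage = f"nmr[{cultivar}]"
            comp = nm.compare_betaine(
                nmr[cultivar][2017], nmr[cultivar][2018], mode=config.betaine_mode
            )

            rank_by_name = {s.variable_name: s for s in fitted.kw_scores}
            report["cultivars"][cultivar] = {
                "n_samples": table.n_samples,
                "isotope_tests": iso_stats,
                "selected_variables": [
                    {"variable": v, "H": rank_by_name[v].H, "rank": rank_by_name[v].rank}
                    for v in fitted.selected
                ],
                "explained_variance_pct": fitted.pca.explained_variance_pct.tolist(),
                "full_model_accuracy_pct": full_acc,
                "cv": {
                    "mean_accuracy_pct": cv.mean_accuracy,
                    "n_iterations": cv.n_iterations,
                    "train_fraction": cv.train_fraction,
                    "accuracies": cv.accuracies.tolist(),
                },
                "betaine": {
                    "test": _test_result_dict(comp.test),
                    "all_2018_higher": comp.all_2018_higher,
                },
            }
            report["cultivars"][cultivar]["_fitted"] = fitted  # not serialized

        stage = "climate"
        for year, wx in sorted(weather.items()):
            annual_precip, annual_tmean, _ = ci.aggregate(wx, "annual")
            jja_precip, _, hot_days = ci.aggregate(wx, "jja")
            idm = ci.de_martonne(annual_precip, annual_tmean)
            report["climate"][str(year)] = {
                "annual_precip_mm": annual_precip,
                "annual_tmean_C": annual_tmean,
                "jja_precip_mm": jja_precip,
                "jja_hot_days": hot_days,
                "I_DM": idm,
                "aridity_class": ci.classify_aridity(idm),
                "annual_pct_of_reference": ci.percent_of_reference(
                    annual_precip, REFERENCE_PRECIP_ANNUAL
                ),
                "jja_pct_of_reference": ci.percent_of_reference(
                    jja_precip, REFERENCE_PRECIP_SUMMER
                ),
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if out_dir is not None:
        _write_artifacts(report, config, out_dir)
    return report


def _serializable(report: dict) -> dict:
    out = json.loads(json.dumps(
        {k: v for k, v in report.items()},
        default=lambda o: None if isinstance(o, fc.FittedPipeline) else str(o),
        sort_keys=True,
    ))
    for cv in out.get("cultivars", {}).values():
        cv.pop("_fitted", None)
    return out


def _write_artifacts(report: dict, config: RunConfig, out_dir: str) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(_serializable(report), fh, indent=2, sort_keys=True)
    for cultivar, block in report["cultivars"].items():
        fitted: fc.FittedPipeline = block["_fitted"]
        pd.DataFrame(block["selected_variables"]).to_csv(
            out / f"selected_variables_{cultivar}.csv", index=False
        )
        pd.DataFrame(
            fitted.scores_train, columns=["PC1", "PC2"][: fitted.scores_train.shape[1]]
        ).to_csv(out / f"scores_{cultivar}.csv", index=False)
        pd.DataFrame(
            fitted.pca.loadings,
            columns=[f"PC{i+1}" for i in range(fitted.pca.loadings.shape[1])],
            index=fitted.pca.variable_names,
        ).to_csv(out / f"loadings_{cultivar}.csv")
        pd.DataFrame(
            {"accuracy_pct": block["cv"]["accuracies"]}
        ).to_csv(out / f"cv_accuracies_{cultivar}.csv", index=False)


def _config_hash(config: RunConfig) -> str:
    d = asdict(config)
    if config.generator is not None:
        d["generator"] = sd.config_to_dict(config.generator)
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def variable_importance_report(report: dict, cultivar: str) -> pd.DataFrame:
    """Selected variables sorted by H descending, flagging which of the six
    drought-sensitive band regions (and which isotope variables) appear."""
    block = report["cultivars"][cultivar]
    rows = []
    for entry in sorted(block["selected_variables"], key=lambda e: e["rank"]):
        name = entry["variable"]
        band = ""
        if name.startswith("bin_"):
            center = float(name[4:])
            near = [b for b in BAND_CENTERS if abs(center - b) <= 150.0]
            if near:
                band = f"{near[0]:.0f}"
        elif name in fc.ISOTOPE_VARS:
            band = "isotope"
        rows.append(
            {"variable": name, "H": entry["H"], "rank": entry["rank"],
             "band_region": band}
        )
    return pd.DataFrame(rows)
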