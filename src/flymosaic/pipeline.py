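"""Stage orchestration: generate inputs, run each analysis, write reports.

Each ``run_*`` function consumes a :class:`~flymosaic.config.RunConfig`,
reads its inputs from disk (or generates synthetic ones when no paths are
configured), executes the corresponding analysis module, and writes CSV/JSON
reports carrying a provenance block (package version, seed, config hash).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Dict, List, Tuple

import numpy as np
import pandas as pd

from . import choices as choices_mod
from . import mosaic as mosaic_mod
from . import synth, vision
from .config import RunConfig
from .errors import InputError
from .spectra import (
    ReceptorSet,
    Spectrum,
    WavelengthGrid,
    d65_illuminant,
    equal_energy_illuminant,
    nomogram_receptor_set,
    read_spectra_csv,
    receptor_set_from_csv,
    resample,
    write_spectra_csv,
)

logger = logging.getLogger(__name__)

#: The soil each flower color is normally displayed on in the field.
NATIVE_SOIL = {"orange": "pale", "white": "red"}


def _illuminant(config: RunConfig) -> Spectrum:
    grid = config.grid
    choice = config["illuminant"]
    if choice == "d65":
        return d65_illuminant(grid, photon_units=bool(config["photon_units"]))
    if choice == "equal_energy":
        return equal_energy_illuminant(grid)
    spectra = read_spectra_csv(choice, kind="illuminant")
    label, spec = next(iter(spectra.items()))
    return resample(spec, grid)


def _receptors(config: RunConfig) -> ReceptorSet:
    grid = config.grid
    rcfg = config["receptors"]
    if rcfg.get("source") == "file":
        return receptor_set_from_csv(rcfg["path"], grid)
    return nomogram_receptor_set(rcfg.get("lambda_max"), grid)


def _write_json(path: Path, payload: Dict[str, Any], config: RunConfig) -> None:
    payload = {"provenance": config.provenance(), **payload}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# generate
# ---------------------------------------------------------------------------

def generate_spectra_bundle(
    config: RunConfig, out_dir: Path
) -> Tuple[Path, Path]:
    """Write a synthetic spectra CSV and per-image region manifest.

    For every species x soil combination, ``n_images`` replicate images are
    emulated, each with ``n_regions`` floret-region spectra and one soil
    background spectrum (all independently noisy, seeded deterministically).
    """
    grid = config.grid
    n_images = int(config["vision"]["n_images"])
    n_regions = int(config["vision"]["n_regions"])
    rng = np.random.default_rng(config.seed)
    spectra: Dict[str, Spectrum] = {}
    manifest_rows: List[Dict[str, Any]] = []
    for species in sorted(synth.SPECIES_COLORS):
        params = synth.species_spectrum_params(species)
        for soil in ("pale", "red"):
            soil_params = synth.DEFAULT_SPECTRUM_PARAMS[f"{soil}_soil"]
            for img in range(1, n_images + 1):
                image_id = f"{species}_{soil}_{img:02d}"
                bg_label = f"{image_id}_bg"
                spectra[bg_label] = synth.gen_spectrum(
                    soil_params, grid, seed=int(rng.integers(2**31))
                )
                manifest_rows.append(
                    {"image_id": image_id, "species": species, "soil": soil,
                     "region_id": "background", "spectrum_label": bg_label}
                )
                for region in range(1, n_regions + 1):
                    label = f"{image_id}_r{region}"
                    spectra[label] = synth.gen_spectrum(
                        params, grid, seed=int(rng.integers(2**31))
                    )
                    manifest_rows.append(
                        {"image_id": image_id, "species": species, "soil": soil,
                         "region_id": f"region_{region}", "spectrum_label": label}
                    )
    spectra_path = out_dir / "spectra.csv"
    manifest_path = out_dir / "manifest.csv"
    write_spectra_csv(spectra_path, spectra)
    pd.DataFrame(manifest_rows).to_csv(manifest_path, index=False)
    return spectra_path, manifest_path


def generate_landscape_bundle(config: RunConfig, out_dir: Path) -> Tuple[Path, Path]:
    params = synth.LandscapeParams(seed=config.seed, **config["mosaic"]["landscape"])
    records, site_colors = synth.gen_landscape(params)
    surveys, colors = synth.landscape_frames(records, site_colors)
    surveys_path = out_dir / "surveys.csv"
    colors_path = out_dir / "site_colors.csv"
    surveys.to_csv(surveys_path, index=False)
    colors.to_csv(colors_path, index=False)
    return surveys_path, colors_path


def generate_choices_bundle(config: RunConfig, out_dir: Path) -> Path:
    params = synth.ChoiceSimParams(seed=config.seed, **config["choice"]["sim"])
    trials = synth.gen_choices(params)
    trials_path = out_dir / "choices.csv"
    trials.to_csv(trials_path, index=False)
    return trials_path


# ---------------------------------------------------------------------------
# vision stage
# ---------------------------------------------------------------------------

def run_vision(config: RunConfig, out_dir: str | Path, plot: bool = False) -> Dict[str, Any]:
    """Model every image in the manifest and write points/centroid/Welch reports."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vcfg = config["vision"]
    if vcfg.get("spectra") and vcfg.get("manifest"):
        spectra_path, manifest_path = Path(vcfg["spectra"]), Path(vcfg["manifest"])
        for p in (spectra_path, manifest_path):
            if not p.exists():
                raise InputError(f"missing input file: {p}")
    else:
        spectra_path, manifest_path = generate_spectra_bundle(config, out_dir)

    spectra = read_spectra_csv(spectra_path, kind="reflectance")
    manifest = pd.read_csv(manifest_path)
    required = {"image_id", "species", "soil", "region_id", "spectrum_label"}
    missing_cols = required - set(manifest.columns)
    if missing_cols:
        raise InputError(f"manifest missing columns: {sorted(missing_cols)}")

    grid = config.grid
    illuminant = _illuminant(config)
    receptors = _receptors(config)
    thresholds = {str(k): float(v) for k, v in config["thresholds"].items()}
    transform = config["transform"]

    point_rows = []
    clouds: Dict[Tuple[str, str], List[vision.VisionPoint]] = {}
    for image_id, group in manifest.groupby("image_id", sort=True):
        for i, row in group.iterrows():
            if row["spectrum_label"] not in spectra:
                raise InputError(
                    f"manifest line {i + 2}: spectrum label "
                    f"{row['spectrum_label']!r} not found in {spectra_path.name}"
                )
        bg_rows = group[group["region_id"] == "background"]
        if len(bg_rows) != 1:
            raise InputError(
                f"image {image_id!r} needs exactly one background row, "
                f"found {len(bg_rows)}"
            )
        species = str(group["species"].iloc[0])
        soil = str(group["soil"].iloc[0])
        background = resample(spectra[str(bg_rows["spectrum_label"].iloc[0])], grid)
        regions = [
            resample(spectra[str(r["spectrum_label"])], grid)
            for _, r in group[group["region_id"] != "background"].iterrows()
        ]
        if not regions:
            raise InputError(f"image {image_id!r} has no floret regions")
        point = vision.region_mean_point(regions, background, illuminant, receptors,
                                         transform=transform)
        verdict = vision.detectability_verdict(point, thresholds)
        point_rows.append(
            {"image_id": image_id, "species": species, "soil": soil,
             "x": point.x, "y": point.y, "quadrant": point.quadrant,
             "dist_origin": point.dist_origin, "verdict": verdict}
        )
        clouds.setdefault((species, soil), []).append(point)

    points = pd.DataFrame(point_rows)
    points_path = out_dir / "points.csv"
    points.to_csv(points_path, index=False)

    species_clouds = {
        key: vision.SpeciesCloud(species=f"{key[0]}@{key[1]}", points=pts)
        for key, pts in clouds.items()
    }
    soils = sorted({soil for _, soil in species_clouds})
    all_species = sorted({sp for sp, _ in species_clouds})
    dist_rows = []
    for soil in soils:
        for sa in all_species:
            row: Dict[str, Any] = {"soil": soil, "species": sa}
            for sb in all_species:
                ca, cb = species_clouds.get((sa, soil)), species_clouds.get((sb, soil))
                row[sb] = (
                    vision.centroid_distance(ca, cb) if ca and cb else np.nan
                )
            dist_rows.append(row)
    centroid_path = out_dir / "centroid_distances.csv"
    pd.DataFrame(dist_rows).to_csv(centroid_path, index=False)

    welch: Dict[str, Any] = {}
    one_sided = bool(config["one_sided_welch"])
    for species in all_species:
        color = synth.SPECIES_COLORS.get(species)
        native = NATIVE_SOIL.get(color or "", soils[0])
        foreign = [s for s in soils if s != native]
        if (species, native) not in species_clouds or not foreign:
            continue
        d_native = [p.dist_origin for p in species_clouds[(species, native)].points]
        d_foreign = [
            p.dist_origin
            for s in foreign
            for p in species_clouds[(species, s)].points
        ]
        if len(d_native) < 2 or len(d_foreign) < 2:
            continue
        res = vision.welch_t(d_native, d_foreign, one_sided=one_sided)
        welch[species] = {
            "native_soil": native, "t": res.t, "df": res.df, "p": res.p,
            "mean_native": float(np.mean(d_native)),
            "mean_foreign": float(np.mean(d_foreign)),
        }
    report = {
        "n_images": int(points.shape[0]),
        "clouds": {
            f"{sp}@{soil}": {
                "n": len(c.points),
                "centroid_x": c.centroid[0],
                "centroid_y": c.centroid[1],
                "quadrants": sorted({p.quadrant for p in c.points}),
            }
            for (sp, soil), c in sorted(species_clouds.items())
        },
        "welch_native_vs_foreign": welch,
        "outputs": {"points": str(points_path), "centroids": str(centroid_path)},
    }
    _write_json(out_dir / "vision_report.json", report, config)
    if plot:
        _plot_points(points, out_dir / "points.png")
    return report


def _plot_points(points: pd.DataFrame, path: Path) -> None:
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise InputError("plotting requires matplotlib (install flymosaic[plot])") from exc
    fig, ax = plt.subplots(figsize=(5, 5))
    for (species, soil), grp in points.groupby(["species", "soil"]):
        ax.scatter(grp["x"], grp["y"], label=f"{species} ({soil})", s=18, alpha=0.8)
    ax.axhline(0, color="0.6", lw=0.8)
    ax.axvline(0, color="0.6", lw=0.8)
    ax.set_xlabel("p opponency (R7p - R8p excitation)")
    ax.set_ylabel("y opponency (R7y - R8y excitation)")
    ax.set_xlim(-1, 1)
    ax.set_ylim(-1, 1)
    ax.legend(fontsize=6, loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# mosaic stage
# ---------------------------------------------------------------------------

def _fit_payload(fit: mosaic_mod.LogisticFit) -> Dict[str, Any]:
    payload = {
        "method": fit.method,
        "converged": bool(fit.converged),
        "separated": bool(fit.separated),
        "coef": dict(zip(fit.names, fit.coef.tolist())),
        "se": dict(zip(fit.names, fit.se.tolist())),
        "z": dict(zip(fit.names, fit.z.tolist())),
        "p": dict(zip(fit.names, fit.p.tolist())),
        "loglik": fit.loglik,
    }
    if fit.lr_stat is not None:
        payload["lr_stat"] = dict(zip(fit.names, fit.lr_stat.tolist()))
        payload["lr_p"] = dict(zip(fit.names, fit.lr_p.tolist()))
    return payload


def run_mosaic(config: RunConfig, out_dir: str | Path) -> Dict[str, Any]:
    """Site densities + color coding + MLE and Firth logistic fits."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mcfg = config["mosaic"]
    if mcfg.get("surveys") and mcfg.get("site_colors"):
        surveys_path, colors_path = Path(mcfg["surveys"]), Path(mcfg["site_colors"])
        for p in (surveys_path, colors_path):
            if not p.exists():
                raise InputError(f"missing input file: {p}")
    else:
        surveys_path, colors_path = generate_landscape_bundle(config, out_dir)

    surveys = pd.read_csv(surveys_path)
    if surveys.empty:
        raise InputError(f"survey file {surveys_path} is empty")
    colors = pd.read_csv(colors_path)
    records = [
        mosaic_mod.SurveyRecord(
            site_id=str(r["site_id"]), plant_species=str(r["plant_species"]),
            flies_per_flowerhead=float(r["flies_per_flowerhead"]),
            flowerheads_per_m2=float(r["flowerheads_per_m2"]),
            fly_species=str(r["fly_species"]),
        )
        for _, r in surveys.iterrows()
    ]
    site_colors: Dict[str, List[str]] = {}
    for _, r in colors.iterrows():
        site_colors.setdefault(str(r["site_id"]), []).append(str(r["color"]))

    report: Dict[str, Any] = {"models": {}}
    summaries = {}
    for fly in ("M_capensis", "C_nigripes"):
        summary = mosaic_mod.site_summaries(records, site_colors, fly)
        summaries[fly] = summary
        summary.to_csv(out_dir / f"site_summary_{fly}.csv", index=False)

    # Model 1: orange presence ~ focal (orange-community) fly density.
    # Model 2: white presence ~ alternate (white-community) fly density.
    model_specs = [
        ("orange_vs_M_capensis", "M_capensis", lambda code: code),
        ("white_vs_C_nigripes", "C_nigripes", lambda code: 1 - code),
    ]
    for name, fly, transform in model_specs:
        summary = summaries[fly]
        y = transform(summary["color_code"].to_numpy())
        x = summary["fly_density"].to_numpy()
        names = ["intercept", "fly_density"]
        entry: Dict[str, Any] = {"n_sites": int(summary.shape[0])}
        try:
            entry["mle"] = _fit_payload(mosaic_mod.logistic_fit_mle(y, x, names=names))
        except Exception as exc:  # degenerate synthetic draws surface as text
            entry["mle"] = {"error": str(exc)}
        try:
            entry["firth"] = _fit_payload(mosaic_mod.logistic_fit_firth(y, x, names=names))
        except Exception as exc:
            entry["firth"] = {"error": str(exc)}
        report["models"][name] = entry

    report["max_density"] = {
        fly: float(summaries[fly]["fly_density"].max()) for fly in summaries
    }
    _write_json(out_dir / "mosaic_report.json", report, config)
    return report


# ---------------------------------------------------------------------------
# choice stage
# ---------------------------------------------------------------------------

def run_choice(config: RunConfig, out_dir: str | Path) -> Dict[str, Any]:
    """GEE preference model, EMMs, first-choice tests, conditioning contrast."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ccfg = config["choice"]
    if ccfg.get("trials"):
        trials_path = Path(ccfg["trials"])
        if not trials_path.exists():
            raise InputError(f"missing input file: {trials_path}")
    else:
        trials_path = generate_choices_bundle(config, out_dir)
    trials = pd.read_csv(trials_path)
    if trials.empty:
        raise InputError(f"choice file {trials_path} is empty")

    jackknife = ccfg.get("jackknife", "one-step")
    fit = choices_mod.fit_choice_model(
        trials, terms=("species", "soil", "species:soil"), jackknife=jackknife
    )
    wald = {
        term: dict(zip(("wald", "df", "p"), choices_mod.wald_test(fit, term)))
        for term in ("species", "soil", "species:soil")
    }
    emms = {}
    for species in fit.factors["species"]:
        emm, (lo, hi) = choices_mod.emmeans(fit, {"species": species})
        emms[species] = {"p_orange": emm, "ci_low": lo, "ci_high": hi}

    # First-choice soil counts (detectability experiment analog): the soil of
    # each fly's first recorded choice, tested per species against 50:50.
    first = trials[trials["choice_order"] == 1] if "choice_order" in trials else (
        trials.groupby("fly_id").head(1)
    )
    first_choice = {}
    for species, group in first.groupby("fly_species"):
        n_red = int((group["soil"] == "red").sum())
        n_pale = int((group["soil"] == "pale").sum())
        stat, df, p = choices_mod.first_choice_chisq(n_red, n_pale)
        first_choice[str(species)] = {
            "n_red": n_red, "n_pale": n_pale, "chisq": stat, "df": df, "p": p,
        }

    report = {
        "n_choices": int(fit.n_obs),
        "n_flies": int(fit.n_clusters),
        "excluded_flies": fit.excluded_flies,
        "alpha": fit.alpha,
        "phi": fit.phi,
        "coef": dict(zip(fit.colnames, fit.coef.tolist())),
        "se": dict(zip(fit.colnames, fit.se().tolist())),
        "wald": wald,
        "emmeans": emms,
        "first_choice": first_choice,
    }
    _write_json(out_dir / "choice_report.json", report, config)
    return report
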