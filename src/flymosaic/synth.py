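"""Synthetic spectra, landscape surveys, and choice sequences.

The study's field data (floret/soil reflectance spectra, site surveys, and
choice records) are not deposited, so this module generates stand-in data
with the statistical structure the analyses assume:

* spectra built from named shape components (a sigmoidal reflectance step,
  Gaussian peaks, truncated Gaussian noise) that emulate white daisies (high
  flat reflectance across 400-700 nm), orange daisies (reflectance step near
  560 nm plus a secondary near-UV peak around 330-370 nm), pale granite soil,
  and red sand;
* landscape surveys where per-site fly densities follow a zero-inflated
  log-normal and site flower color follows a logistic law in density, with an
  optional complete-separation regime (orange present only where the
  white-community fly is absent);
* choice sequences with beta-mixed per-fly preferences, which induce exactly
  the exchangeable within-fly correlation the GEE assumes (alpha = 1/(a+b+1)
  for a Beta(a, b) mixing law).

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import DomainError, InputError
from .mosaic import SurveyRecord
from .spectra import DEFAULT_GRID, Spectrum, WavelengthGrid

SPECTRUM_KINDS = ("white_flower", "orange_flower", "pale_soil", "red_soil")


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectrumParams:
    """Shape parameters for one synthetic reflectance spectrum.

    The spectrum is ``base + step + sum(Gaussians) + noise`` clipped to
    [0, 1]: ``base`` is a flat floor, the step is a logistic rise of height
    ``step_height`` centered at ``step_center_nm`` with slope width
    ``step_width_nm``, and each Gaussian peak has (amplitude, center nm,
    sd nm).  ``noise_sd`` is the sd of additive Gaussian measurement noise.
    """

    kind: str
    base: float = 0.02
    step_height: float = 0.0
    step_center_nm: float = 450.0
    step_width_nm: float = 15.0
    peaks: Tuple[Tuple[float, float, float], ...] = ()
    noise_sd: float = 0.005

    def __post_init__(self) -> None:
        if self.kind not in SPECTRUM_KINDS:
            raise DomainError(f"unknown spectrum kind {self.kind!r}")
        if self.base < 0 or self.step_height < 0 or self.noise_sd < 0:
            raise DomainError("amplitudes and noise sd must be nonnegative")
        for amp, center, sd in self.peaks:
            if amp < 0 or sd <= 0:
                raise DomainError("peak amplitudes must be >= 0 and widths > 0")


#: Default shapes.  White daisies: high plateau from ~400 nm, UV-dark.
#: Orange daisies: dark below ~550 nm, bright above, secondary near-UV peak.
#: Pale granite soil: moderately bright, gently rising.  Red sand: dark in
#: the short wavelengths, rising towards the red.
DEFAULT_SPECTRUM_PARAMS: Dict[str, SpectrumParams] = {
    "white_flower": SpectrumParams(
        kind="white_flower", base=0.05, step_height=0.80,
        step_center_nm=410.0, step_width_nm=12.0,
    ),
    "orange_flower": SpectrumParams(
        kind="orange_flower", base=0.04, step_height=0.60,
        step_center_nm=565.0, step_width_nm=18.0,
        peaks=((0.22, 350.0, 22.0),),
    ),
    "pale_soil": SpectrumParams(
        kind="pale_soil", base=0.25, step_height=0.18,
        step_center_nm=480.0, step_width_nm=80.0,
    ),
    "red_soil": SpectrumParams(
        kind="red_soil", base=0.06, step_height=0.38,
        step_center_nm=590.0, step_width_nm=45.0,
    ),
}


def gen_spectrum(
    params: SpectrumParams,
    grid: WavelengthGrid = DEFAULT_GRID,
    seed: int = 0,
) -> Spectrum:
    """Generate one synthetic reflectance spectrum (deterministic per seed)."""
    rng = np.random.default_rng(seed)
    wl = grid.wavelengths
    values = np.full(wl.shape, params.base)
    if params.step_height > 0:
        values = values + params.step_height / (
            1.0 + np.exp(-(wl - params.step_center_nm) / params.step_width_nm)
        )
    for amp, center, sd in params.peaks:
        values = values + amp * np.exp(-0.5 * ((wl - center) / sd) ** 2)
    if params.noise_sd > 0:
        values = values + rng.normal(0.0, params.noise_sd, size=wl.shape)
    values = np.clip(values, 0.0, 1.0)
    return Spectrum(grid, values, kind="reflectance", label=params.kind)


def species_spectrum_params(species: str) -> SpectrumParams:
    """Per-species variants of the default flower shapes.

    The two orange species differ in the position and intensity of the
    secondary near-UV peak, while the two white species are nearly identical
    — the qualitative contrast seen between the study genera.
    """
    base = {
        "D_sinuata": replace(DEFAULT_SPECTRUM_PARAMS["orange_flower"],
                             peaks=((0.22, 350.0, 22.0),)),
        "U_cakilefolia": replace(DEFAULT_SPECTRUM_PARAMS["orange_flower"],
                                 peaks=((0.30, 336.0, 20.0),)),
        "D_pluvialis": DEFAULT_SPECTRUM_PARAMS["white_flower"],
        "U_speciosa": replace(DEFAULT_SPECTRUM_PARAMS["white_flower"],
                              step_height=0.78),
    }
    if species not in base:
        raise InputError(f"unknown species {species!r} (have {sorted(base)})")
    return base[species]


SPECIES_COLORS = {
    "D_sinuata": "orange", "U_cakilefolia": "orange",
    "D_pluvialis": "white", "U_speciosa": "white",
}


# ---------------------------------------------------------------------------
# Landscape surveys
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LandscapeParams:
    """Generating law for site surveys.

    Fly densities (individuals per m2) per site follow a zero-inflated
    log-normal; P(orange site) = logit^-1(beta0 + beta1 * focal density).
    Defaults give the focal (orange-community) fly a density distribution
    whose upper range reaches the printed field maxima (~1.7 per m2) at the
    study's 54 sites, and the alternate fly a higher-density law (~3.7 max).
    ``separation_mode`` instead codes a site orange exactly when the
    white-community fly is absent, reproducing complete separation.
    """

    n_sites: int = 54
    beta0: float = -1.5
    beta1: float = 3.0
    p_absent: float = 0.35            # zero-inflation of the focal fly
    meanlog: float = np.log(0.35)     # log-normal location of the focal fly
    sdlog: float = 0.9
    alt_p_absent: float = 0.5         # the other fly species
    alt_meanlog: float = np.log(0.8)
    alt_sdlog: float = 0.9
    plants_per_site: int = 3
    separation_mode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise DomainError("need at least 2 sites")
        if not (0 <= self.p_absent < 1 and 0 <= self.alt_p_absent < 1):
            raise DomainError("absence probabilities must be in [0, 1)")
        if self.plants_per_site < 1:
            raise DomainError("need at least 1 plant species per site")


def _factor_density(
    rng: np.random.Generator, density: float, n_plants: int, site: str, fly: str
) -> List[SurveyRecord]:
    """Split a site density across plant species as load x flowerhead-density
    pairs whose products sum back to the drawn density exactly."""
    records = []
    if density == 0.0:
        shares = np.zeros(n_plants)
    else:
        shares = density * rng.dirichlet(np.ones(n_plants) * 2.0)
    for j in range(n_plants):
        heads = float(rng.uniform(2.0, 30.0))  # flowerheads per m2
        records.append(
            SurveyRecord(
                site_id=site,
                plant_species=f"plant_{j + 1}",
                flies_per_flowerhead=float(shares[j] / heads),
                flowerheads_per_m2=heads,
                fly_species=fly,
            )
        )
    return records


def gen_landscape(
    params: LandscapeParams, return_densities: bool = False
) -> Tuple[List[SurveyRecord], Dict[str, List[str]]] | Tuple[
    List[SurveyRecord], Dict[str, List[str]], Dict[str, Dict[str, float]]
]:
    """Generate survey records and site flower colors.

    Returns ``(records, site_colors)`` where ``site_colors`` maps site id to
    the list of focal-species colors present (one color per site — colors do
    not co-occur, matching the binary coding's assumption).  With
    ``return_densities`` the drawn per-site densities are also returned, so
    the flies-per-flowerhead x flowerheads-per-m2 factorization can be
    checked to reassemble them exactly.
    """
    rng = np.random.default_rng(params.seed)
    records: List[SurveyRecord] = []
    site_colors: Dict[str, List[str]] = {}
    densities: Dict[str, Dict[str, float]] = {}
    for i in range(params.n_sites):
        site = f"site_{i + 1:03d}"
        present = rng.random() >= params.p_absent
        density = float(np.exp(rng.normal(params.meanlog, params.sdlog))) if present else 0.0
        alt_present = rng.random() >= params.alt_p_absent
        alt_density = (
            float(np.exp(rng.normal(params.alt_meanlog, params.alt_sdlog)))
            if alt_present else 0.0
        )
        records.extend(
            _factor_density(rng, density, params.plants_per_site, site, "M_capensis")
        )
        records.extend(
            _factor_density(rng, alt_density, params.plants_per_site, site, "C_nigripes")
        )
        densities[site] = {"M_capensis": density, "C_nigripes": alt_density}
        if params.separation_mode:
            orange = alt_density == 0.0
        else:
            p_orange = 1.0 / (1.0 + np.exp(-(params.beta0 + params.beta1 * density)))
            orange = rng.random() < p_orange
        site_colors[site] = ["orange" if orange else "white"]
    if return_densities:
        return records, site_colors, densities
    return records, site_colors


def landscape_frames(
    records: Sequence[SurveyRecord], site_colors: Dict[str, List[str]]
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Survey records and site colors as the CSV-dialect DataFrames."""
    surveys = pd.DataFrame(
        [
            {
                "site_id": r.site_id,
                "fly_species": r.fly_species,
                "plant_species": r.plant_species,
                "flies_per_flowerhead": r.flies_per_flowerhead,
                "flowerheads_per_m2": r.flowerheads_per_m2,
            }
            for r in records
        ]
    )
    colors = pd.DataFrame(
        [
            {"site_id": s, "color": c}
            for s, cs in sorted(site_colors.items())
            for c in cs
        ]
    )
    return surveys, colors


# ---------------------------------------------------------------------------
# Choice sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChoiceSimParams:
    """Generating law for choice experiments.

    Each fly draws a latent orange preference p_i from a Beta law with the
    species' marginal mean and common concentration ``a + b``; its choices
    are then i.i.d. Bernoulli(p_i), which induces exchangeable within-fly
    correlation alpha = 1 / (a + b + 1).  Sequence lengths are geometric with
    median ~5, truncated at 20 (arena trials stopped at 20 choices); soils
    alternate at random per choice.  Default fly counts and preferences
    mirror the study's Ursinia experiment (47 and 20 flies; orange chosen
    with probability 0.91 by the orange-community fly, 0.20 by the
    white-community fly, i.e., an 80% white preference).
    """

    n_flies: Dict[str, int] = field(
        default_factory=lambda: {"M_capensis": 47, "C_nigripes": 20}
    )
    preference: Dict[str, float] = field(
        default_factory=lambda: {"M_capensis": 0.91, "C_nigripes": 0.20}
    )
    concentration: float = 10.0       # a + b of the Beta mixing law
    median_choices: int = 5
    max_choices: int = 20
    genus_pair: str = "Ursinia"
    phase: str = "pre"
    p_red_soil: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for sp, pref in self.preference.items():
            if not (0.0 < pref < 1.0):
                raise DomainError(f"preference for {sp} must be in (0, 1)")
        for sp, n in self.n_flies.items():
            if n < 2:
                raise DomainError(f"need at least 2 flies per species (got {n} for {sp})")
        if self.concentration <= 0:
            raise DomainError("Beta concentration must be positive")
        if not (1 <= self.median_choices <= self.max_choices):
            raise DomainError("median choices must lie in [1, max_choices]")

    @property
    def exchangeable_alpha(self) -> float:
        """Within-fly correlation implied by the Beta mixing law."""
        return 1.0 / (self.concentration + 1.0)


def _sequence_length(rng: np.random.Generator, median: int, cap: int) -> int:
    # geometric with the requested median, truncated at the arena cap
    p = 1.0 - 0.5 ** (1.0 / median)
    return int(min(rng.geometric(p), cap))


def gen_choices(params: ChoiceSimParams, fly_id_offset: int = 0) -> pd.DataFrame:
    """Generate a long-format choice table (one row per recorded choice)."""
    rng = np.random.default_rng(params.seed)
    rows = []
    fly_counter = fly_id_offset
    for species in sorted(params.n_flies):
        pref = params.preference[species]
        a = pref * params.concentration
        b = (1.0 - pref) * params.concentration
        for _ in range(params.n_flies[species]):
            fly_counter += 1
            fly = f"fly_{fly_counter:04d}"
            p_i = rng.beta(a, b)
            length = _sequence_length(rng, params.median_choices, params.max_choices)
            for order in range(1, length + 1):
                rows.append(
                    {
                        "fly_id": fly,
                        "fly_species": species,
                        "genus_pair": params.genus_pair,
                        "phase": params.phase,
                        "choice_order": order,
                        "flower_color": "orange" if rng.random() < p_i else "white",
                        "soil": "red" if rng.random() < params.p_red_soil else "pale",
                    }
                )
    return pd.DataFrame(rows)


def gen_conditioning_choices(
    params: ChoiceSimParams,
    post_preference: Optional[Dict[str, float]] = None,
    post_phase: str = "post_1h",
) -> pd.DataFrame:
    """Pre- and post-conditioning choices for the same flies.

    Each fly keeps its identity across phases (clusters span both phases);
    ``post_preference`` defaults to the pre-phase preferences, i.e., a null
    conditioning effect.
    """
    rng = np.random.default_rng(params.seed)
    post_pref = dict(params.preference)
    if post_preference:
        post_pref.update(post_preference)
    rows = []
    fly_counter = 0
    for species in sorted(params.n_flies):
        pref_pre = params.preference[species]
        pref_post = post_pref[species]
        for _ in range(params.n_flies[species]):
            fly_counter += 1
            fly = f"fly_{fly_counter:04d}"
            for phase, pref in (("pre", pref_pre), (post_phase, pref_post)):
                a = pref * params.concentration
                b = (1.0 - pref) * params.concentration
                p_i = rng.beta(a, b)
                length = _sequence_length(rng, params.median_choices, params.max_choices)
                for order in range(1, length + 1):
                    rows.append(
                        {
                            "fly_id": fly,
                            "fly_species": species,
                            "genus_pair": params.genus_pair,
                            "phase": phase,
                            "choice_order": order,
                            "flower_color": "orange" if rng.random() < p_i else "white",
                            "soil": "red" if rng.random() < params.p_red_soil else "pale",
                        }
                    )
    return pd.DataFrame(rows)
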