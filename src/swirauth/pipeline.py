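"""Config-driven end-to-end study on synthetic plates.

Mirrors the study design of the screening problem: a pure-almond calibration
set (two varieties, 100 half-spectra) trains the DD-SIMCA screen, which is
validated on apricot- and peanut-adulterated sets from both almond varieties
plus an external blind set imaged under perturbed illumination; PLS1 models
are then fitted per adulterant for every pretreatment and validated on two
held-out sets; finally one validation plate per adulterant is rendered as a
per-pixel concentration map.

Every stage is deterministic given the study seed: per-set seeds are derived
from it, and each plate's pixels from the set seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__ as _pkg_version
from .chemmap import map_concentration, render_map, summarize_wells
from .containers import ReferencePair, SpectralSet
from .cube import (
    calibrate_reflectance,
    crop_bands,
    extract_well_spectra,
    segment_background,
    write_spectra_csv,
)
from .ddsimca import DDSimca, select_factors
from .metrics import accuracy, confusion, sensitivity, specificity, summarize_concentrations
from .plsr import PLS1Regression, evaluate
from .preprocess import METHODS, SpectralPreprocessor
from .simulate import MixtureDesign, NoiseModel, PlateLayout, render_plate_cube

logger = logging.getLogger(__name__)

BAND_WINDOW_NM = (935.0, 1965.0)


@dataclass(frozen=True)
class SetDesign:
    """One specimen set: adulterant, almond variety and well concentrations."""

    name: str
    adulterant: str
    variety: str
    well_concentrations: tuple
    noise_slope_factor: float = 1.0

    @property
    def n_wells(self) -> int:
        return len(self.well_concentrations)


@dataclass
class StudyConfig:
    """Everything a study run needs; serializable to YAML."""

    seed: int = 0
    layout: PlateLayout = field(default_factory=PlateLayout)
    noise: NoiseModel = field(default_factory=NoiseModel)
    sets: tuple = ()
    alpha: float = 0.01
    gamma: float = 0.01
    ddsimca_factors: object = 2
    ddsimca_max_factors: int = 10
    ddsimca_preprocess: str = "snv"
    plsr_max_factors: int = 12
    plsr_methods: tuple = tuple(m for m in METHODS if m != "sg_smooth")
    sg_window: int = 11
    sg_polyorder: int = 2
    out_dir: str = "study_out"

    def to_yaml(self, path) -> Path:
        path = Path(path)
        d = dataclasses.asdict(self)
        d["layout"] = dataclasses.asdict(self.layout)
        d["noise"] = dataclasses.asdict(self.noise)
        d["sets"] = [dataclasses.asdict(s) for s in self.sets]
        path.write_text(yaml.safe_dump(_plain(d), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["layout"] = PlateLayout(**d["layout"])
        d["noise"] = NoiseModel(**d["noise"])
        d["sets"] = tuple(
            SetDesign(
                name=s["name"],
                adulterant=s["adulterant"],
                variety=str(s["variety"]),
                well_concentrations=tuple(s["well_concentrations"]),
                noise_slope_factor=s.get("noise_slope_factor", 1.0),
            )
            for s in d["sets"]
        )
        d["plsr_methods"] = tuple(d["plsr_methods"])
        return cls(**d)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def default_study_config(seed: int = 0, layout: PlateLayout | None = None) -> StudyConfig:
    """The bundled study design.

    DD-SIMCA calibration: 100 pure half-spectra (25 wells per almond
    variety); validation-1: 110 half-spectra at 0-50% in 5% steps;
    validation-2: 50 at {0, 7, 15, 22, 30}%; external blind sets at
    {0, 7, 15, 22, 30, 40, 45, 50}% x 10 with doubled scatter-slope spread.
    PLS1: calibration 66 (6 per concentration), validation-1 44 (4 per
    concentration, same variety), validation-2 44 (second variety). Each
    well yields two half-spectra.
    """
    steps = tuple(float(c) for c in range(0, 55, 5))
    coarse = (0.0, 7.0, 15.0, 22.0, 30.0)
    external = (0.0, 7.0, 15.0, 22.0, 30.0, 40.0, 45.0, 50.0)
    sets = [
        SetDesign("cal_pure_v1", "none", "1", (0.0,) * 25),
        SetDesign("cal_pure_v2", "none", "2", (0.0,) * 25),
    ]
    for adulterant in ("apricot", "peanut"):
        sets += [
            SetDesign(f"val1_{adulterant}", adulterant, "1", tuple(np.repeat(steps, 5))),
            SetDesign(f"val2_{adulterant}", adulterant, "2", tuple(np.repeat(coarse, 5))),
            SetDesign(
                f"external_{adulterant}", adulterant, "1",
                tuple(np.repeat(external, 5)), noise_slope_factor=2.0,
            ),
            SetDesign(f"plsr_cal_{adulterant}", adulterant, "1", tuple(np.repeat(steps, 3))),
            SetDesign(f"plsr_val1_{adulterant}", adulterant, "1", tuple(np.repeat(steps, 2))),
            SetDesign(
                f"plsr_val2_{adulterant}", adulterant, "2",
                tuple(np.repeat(coarse, (5, 5, 4, 4, 4)).astype(float)),
            ),
        ]
    return StudyConfig(
        seed=int(seed),
        layout=layout if layout is not None else PlateLayout(),
        sets=tuple(sets),
    )


@dataclass
class StudyReport:
    """Structured study output; serializes to one deterministic JSON file."""

    ddsimca_validation: pd.DataFrame
    ddsimca_external: pd.DataFrame
    plsr_grid: pd.DataFrame
    concentration_summaries: pd.DataFrame
    map_paths: dict
    map_well_summaries: dict
    metadata: dict

    def to_dict(self) -> dict:
        return _plain(
            {
                "ddsimca_validation": self.ddsimca_validation.to_dict(orient="records"),
                "ddsimca_external": self.ddsimca_external.to_dict(orient="records"),
                "plsr_grid": self.plsr_grid.to_dict(orient="records"),
                "concentration_summaries": self.concentration_summaries.to_dict(
                    orient="records"
                ),
                "map_paths": {k: str(v) for k, v in self.map_paths.items()},
                "map_well_summaries": {
                    k: v.to_dict(orient="records") for k, v in self.map_well_summaries.items()
                },
                "metadata": self.metadata,
            }
        )

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), sort_keys=True, indent=1))
        return path


# ---------------------------------------------------------------------------
# simulation + extraction of one set


def simulate_set(
    design: SetDesign,
    layout: PlateLayout,
    noise: NoiseModel,
    seed: int,
    keep_first_plate: bool = False,
):
    """Render all plates of a set, calibrate, crop and extract half-spectra.

    Wells beyond one plate's capacity spill onto further plates. Returns the
    SpectralSet (and, when requested, the first plate's cropped cube, mask
    and truth table for the mapping stage).
    """
    noise = noise.scaled(design.noise_slope_factor)
    concs = list(design.well_concentrations)
    n_plates = int(np.ceil(len(concs) / layout.capacity))
    plate_seeds = [
        int(s % 2**31) for s in np.random.SeedSequence(seed).generate_state(n_plates)
    ]
    collected, first_plate = None, None
    for p in range(n_plates):
        chunk = concs[p * layout.capacity : (p + 1) * layout.capacity]
        mix = MixtureDesign(
            adulterant=design.adulterant,
            variety=design.variety,
            concentrations_pct=tuple(chunk),
            seed=plate_seeds[p],
        )
        raw, dark, white, truth = render_plate_cube(mix, layout, noise=noise)
        truth = truth.assign(well_id=[f"{design.name}_p{p}_{w}" for w in truth["well_id"]])
        cube = crop_bands(
            calibrate_reflectance(raw, ReferencePair(dark, white)), *BAND_WINDOW_NM
        )
        mask = segment_background(cube)
        sset = extract_well_spectra(cube, mask, truth, halves=True)
        collected = sset if collected is None else collected.concat(sset)
        if keep_first_plate and p == 0:
            first_plate = (cube, mask, truth)
    logger.info(
        "set %-18s: %d wells on %d plate(s) -> %d spectra",
        design.name, len(concs), n_plates, len(collected),
    )
    if keep_first_plate:
        return collected, first_plate
    return collected


# ---------------------------------------------------------------------------
# the study


def run_study(config: StudyConfig, out_dir=None) -> StudyReport:
    """Execute the full study; artifacts land under ``out_dir``."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    for sub in ("spectra", "models", "decisions", "predictions", "maps"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    set_names = [s.name for s in config.sets]
    set_seeds = {
        name: int(s % 2**31)
        for name, s in zip(
            set_names, np.random.SeedSequence(config.seed).generate_state(len(set_names))
        )
    }
    sets: dict[str, SpectralSet] = {}
    plates = {}
    for design in config.sets:
        keep = design.name.startswith("plsr_val1_")
        result = simulate_set(design, config.layout, config.noise, set_seeds[design.name], keep)
        if keep:
            sets[design.name], plates[design.name.removeprefix("plsr_val1_")] = result
        else:
            sets[design.name] = result
        write_spectra_csv(sets[design.name], out / "spectra" / f"{design.name}.csv")

    # ---- DD-SIMCA screening ------------------------------------------------
    cal = sets["cal_pure_v1"].concat(sets["cal_pure_v2"])
    pp = SpectralPreprocessor(
        method=config.ddsimca_preprocess, window=config.sg_window, polyorder=config.sg_polyorder
    )
    if config.ddsimca_factors == "auto":
        factors = select_factors(
            cal, config.ddsimca_max_factors, config.alpha, config.gamma, preprocessor=pp
        )
    else:
        factors = int(config.ddsimca_factors)
    screen = DDSimca(
        n_components=factors, alpha=config.alpha, gamma=config.gamma, preprocessor=pp
    ).fit(cal)
    screen.save(out / "models" / "ddsimca.yaml")
    logger.info(
        "DD-SIMCA: A=%d, Nh=%d, Nv=%d, c_crit=%.2f",
        factors, screen.dof_score_, screen.dof_orth_, screen.c_crit_,
    )

    def _screen_rows(names):
        rows = []
        for name in names:
            sset = sets[name]
            # each validation set also carries 10 fresh pure half-spectra
            decisions = screen.classify(sset)
            decisions.to_csv(out / "decisions" / f"{name}.csv", index=False)
            labels = {
                sid: ("pure" if conc == 0 else "adulterated")
                for sid, conc in zip(sset.meta["specimen_id"], sset.concentrations)
            }
            counts = confusion(decisions, labels)
            adulterated = sset.subset(sset.concentrations > 0)
            acc_by_conc = decisions.merge(sset.meta, on="specimen_id")
            missed = acc_by_conc.query("concentration_pct > 0 and decision == 'accepted'")
            rows.append(
                {
                    "set": name,
                    "n": len(sset),
                    "tp": counts.tp,
                    "fn": counts.fn,
                    "tn": counts.tn,
                    "fp": counts.fp,
                    "sensitivity_pct": sensitivity(counts),
                    "specificity_pct": specificity(counts),
                    "accuracy_pct": accuracy(counts),
                    "missed_concentrations": sorted(
                        missed["concentration_pct"].unique().tolist()
                    ),
                    "min_adulterated_pct": float(adulterated.concentrations.min())
                    if len(adulterated)
                    else None,
                }
            )
        return pd.DataFrame(rows)

    val_names = [f"{v}_{a}" for a in ("apricot", "peanut") for v in ("val1", "val2")]
    ddsimca_validation = _screen_rows(val_names)
    ddsimca_external = _screen_rows([f"external_{a}" for a in ("apricot", "peanut")])

    # ---- PLS1 quantification ----------------------------------------------
    grid_rows = []
    pls_models = {}
    for adulterant in ("apricot", "peanut"):
        cal_set = sets[f"plsr_cal_{adulterant}"]
        for method in config.plsr_methods:
            pp_m = SpectralPreprocessor(
                method=method, window=config.sg_window, polyorder=config.sg_polyorder
            )
            model = PLS1Regression(
                n_components="auto",
                max_components=config.plsr_max_factors,
                preprocessor=pp_m,
            ).fit(cal_set, cal_set.concentrations)
            row = {
                "adulterant": adulterant,
                "method": method,
                "n_factors": model.n_components_,
                "r2_cal": model.fit_report_.r2,
                "sec_pct": model.fit_report_.se,
            }
            for val in ("val1", "val2"):
                vset = sets[f"plsr_{val}_{adulterant}"]
                pred = model.predict(vset)
                report = evaluate(vset.concentrations, pred)
                row[f"r2_pre_{val}"] = report.r2
                row[f"sep_{val}_pct"] = report.se
                pd.DataFrame(
                    {
                        "specimen_id": vset.meta["specimen_id"],
                        "concentration_pct": vset.concentrations,
                        "predicted_pct": pred,
                    }
                ).to_csv(
                    out / "predictions" / f"{adulterant}_{method}_{val}.csv", index=False
                )
            grid_rows.append(row)
            model.save(out / "models" / f"pls1_{adulterant}_{method}.yaml")
            if method == "sg_second":
                pls_models[adulterant] = model
    plsr_grid = pd.DataFrame(grid_rows)

    # ---- concentration maps ------------------------------------------------
    map_paths, map_summaries = {}, {}
    for adulterant, (cube, mask, truth) in plates.items():
        cmap = map_concentration(
            cube, mask, pls_models[adulterant], model_id=f"pls1_{adulterant}_sg_second"
        )
        path = render_map(cmap, out / "maps" / f"map_{adulterant}.png")
        map_paths[adulterant] = path.relative_to(out)  # report stays location-independent
        map_summaries[adulterant] = summarize_wells(cmap, truth)
        logger.info("map %s -> %s", adulterant, path)

    # ---- design summaries --------------------------------------------------
    summary_rows = []
    for name in set_names:
        s = summarize_concentrations(sets[name].concentrations).rounded()
        summary_rows.append(
            {
                "set": name,
                "n": s.n,
                "max_pct": s.maximum,
                "min_pct": s.minimum,
                "mean_pct": s.mean,
                "sd_pct": s.sd,
            }
        )
    concentration_summaries = pd.DataFrame(summary_rows)

    report = StudyReport(
        ddsimca_validation=ddsimca_validation,
        ddsimca_external=ddsimca_external,
        plsr_grid=plsr_grid,
        concentration_summaries=concentration_summaries,
        map_paths=map_paths,
        map_well_summaries=map_summaries,
        metadata={
            "seed": int(config.seed),
            "version": _pkg_version,
            "ddsimca_factors": int(factors),
            "ddsimca_preprocess": config.ddsimca_preprocess,
            "band_window_nm": list(BAND_WINDOW_NM),
            "set_seeds": set_seeds,
        },
    )
    report.save(out / "report.json")
    return report
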