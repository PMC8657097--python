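"""End-to-end dosimetry pipeline: biodistribution tables in, dose reports out.

The pipeline chains the library stages in the order a dosimetry study
runs them: read %IA/g tables and organ masses, build normalized
time-activity curves (sources plus the rest-of-body region), re-apply
physical decay, fit monoexponentials, integrate TIACs with the
conditional rule, compute sphere-model doses for the non-phantom tissues
(and phantom doses when an S-matrix is supplied), optionally rescale the
curves to a second radionuclide and repeat, and emit tumor-to-organ
ratio tables and a difference-ratio comparison against a reference dose
table.

All outputs are deterministic delimited tables without timestamps, so a
rerun with identical inputs is byte-identical.  Tables carry
full-precision columns; display rounding (3 significant figures, integer
difference ratios) is applied only in ``_display`` columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .biodistribution import (
    BiodistributionStudy,
    normalized_curves,
    read_biodistribution,
    read_organ_masses,
)
from .dosimetry import (
    difference_ratio,
    phantom_doses,
    read_svalue_matrix,
    sphere_dose_report,
    tumor_to_organ_ratios,
)
from .kinetics import extrapolate_nuclide, tiac_envelope, to_physical_units
from .nuclides import Nuclide, load_catalog

DEFAULT_SPHERE_TISSUES = ("tumor", "uterus", "ovaries")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    biodistribution: str
    organ_masses: str
    output_dir: str
    nuclide: str = "Cu-64"
    mouse_mass: float = 17.8
    muscle_organ: str = "muscle"
    decay_corrected: bool = True
    fit_scale: str = "log"
    nuclide_catalog: str | None = None
    extrapolate_to: str | None = None
    sphere_tissues: tuple[str, ...] = DEFAULT_SPHERE_TISSUES
    s_matrix: str | None = None
    reference_doses: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.extrapolate_to == self.nuclide:
            raise ValueError("extrapolation target must differ from the source nuclide")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "sphere_tissues" in raw:
            raw["sphere_tissues"] = tuple(raw["sphere_tissues"])
        return cls(**raw)


def _sig3(x: float) -> float:
    if not math.isfinite(x) or x == 0:
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + 2)


def load_study(config: RunConfig) -> tuple[BiodistributionStudy, dict[str, Nuclide]]:
    catalog = load_catalog(config.nuclide_catalog)
    if config.nuclide not in catalog:
        raise ValueError(f"nuclide {config.nuclide!r} not in catalog")
    measurements = read_biodistribution(config.biodistribution)
    masses = read_organ_masses(config.organ_masses)
    study = BiodistributionStudy(
        nuclide=catalog[config.nuclide],
        measurements=measurements,
        organ_masses=masses,
        mouse_mass=config.mouse_mass,
        decay_corrected=config.decay_corrected,
        muscle_organ=config.muscle_organ,
    )
    return study, catalog


def compute_tiacs(
    study: BiodistributionStudy,
    fit_scale: str = "log",
    dest_nuclide: Nuclide | None = None,
) -> pd.DataFrame:
    """TIAC table for every source organ + remainder, optionally rescaled.

    With ``dest_nuclide`` set, the uncorrected curves are first rescaled
    by SF(t_m) to the destination radionuclide, then refitted and
    integrated under that nuclide's physical decay constant.
    """
    curves = normalized_curves(study)
    nuclide = study.nuclide
    rows = []
    for organ, pts in curves.items():
        uncorr = to_physical_units(pts, study.nuclide) if study.decay_corrected else pts
        if dest_nuclide is not None:
            uncorr = list(
                extrapolate_nuclide(uncorr, study.nuclide, dest_nuclide).points
            )
            nuclide = dest_nuclide
        res = tiac_envelope(uncorr, nuclide, scale=fit_scale)
        rows.append(
            {
                "organ": organ,
                "mass_g": study.organ_masses.get(organ, math.nan),
                "tiac_mean": res.tiac_mean,
                "tiac_low": res.tiac_low,
                "tiac_high": res.tiac_high,
                "branch": res.branch,
            }
        )
    table = pd.DataFrame(rows).sort_values("organ").reset_index(drop=True)
    for col in ("tiac_mean", "tiac_low", "tiac_high"):
        table[col + "_display"] = table[col].map(_sig3)
    return table


def _tiac_results(table: pd.DataFrame):
    from .kinetics import TiacResult

    return [
        TiacResult(
            organ=r["organ"],
            tiac_mean=r["tiac_mean"],
            tiac_low=r["tiac_low"],
            tiac_high=r["tiac_high"],
            branch=r["branch"],
            t_last=math.nan,
        )
        for _, r in table.iterrows()
    ]


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run every configured stage; write tables to the output directory.

    Returns the tables keyed by output name (without extension).  Stage
    failures raise with the organ/stage named; tables already written are
    retained.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    study, catalog = load_study(config)
    outputs: dict[str, pd.DataFrame] = {}

    def emit(name: str, table: pd.DataFrame) -> None:
        outputs[name] = table
        table.to_csv(outdir / f"{name}.csv", index=False)

    src = study.nuclide
    tiacs = compute_tiacs(study, config.fit_scale)
    emit(f"tiac_{src.name}", tiacs)

    sphere = sphere_dose_report(
        _tiac_results(tiacs), study.organ_masses, src, list(config.sphere_tissues)
    )
    for col in ("dose_mean", "dose_low", "dose_high"):
        sphere[col + "_display"] = sphere[col].map(_sig3)
    emit(f"dose_sphere_{src.name}", sphere)

    if config.s_matrix:
        smat = read_svalue_matrix(config.s_matrix, nuclide=src.name)
        phantom = phantom_doses(
            _tiac_results(tiacs), smat, fold_into_remainder=list(config.sphere_tissues)
        )
        emit(f"dose_phantom_{src.name}", phantom)

    dest_tables: dict[str, pd.DataFrame] = {}
    if config.extrapolate_to:
        if config.extrapolate_to not in catalog:
            raise ValueError(f"extrapolation nuclide {config.extrapolate_to!r} not in catalog")
        dest = catalog[config.extrapolate_to]
        tiacs_dest = compute_tiacs(study, config.fit_scale, dest_nuclide=dest)
        emit(f"tiac_{dest.name}", tiacs_dest)
        sphere_dest = sphere_dose_report(
            _tiac_results(tiacs_dest), study.organ_masses, dest,
            list(config.sphere_tissues),
        )
        for col in ("dose_mean", "dose_low", "dose_high"):
            sphere_dest[col + "_display"] = sphere_dest[col].map(_sig3)
        emit(f"dose_sphere_{dest.name}", sphere_dest)
        dest_tables["sphere"] = sphere_dest

        if config.reference_doses:
            ref = pd.read_csv(config.reference_doses)
            missing = {"tissue", "dose"} - set(ref.columns)
            if missing:
                raise ValueError(
                    f"reference dose table missing columns: {sorted(missing)}"
                )
            comp_rows = []
            ref_map = dict(zip(ref["tissue"], ref["dose"]))
            for _, r in sphere_dest.iterrows():
                tissue = r["tissue"]
                if tissue not in ref_map:
                    continue
                dr = difference_ratio(r["dose_mean"], ref_map[tissue])
                comp_rows.append(
                    {
                        "tissue": tissue,
                        "tiac": r["tiac"],
                        "dose_extrapolated": r["dose_mean"],
                        "dose_reference": ref_map[tissue],
                        "difference_ratio_pct": dr,
                        "difference_ratio_display": round(dr),
                    }
                )
            emit(f"dose_comparison_{dest.name}", pd.DataFrame(comp_rows))

    ratio_rows = []
    if "tumor" in study.organs():
        for t in study.times():
            for organ, ratio in tumor_to_organ_ratios(study, t).items():
                ratio_rows.append(
                    {
                        "time_h": t,
                        "organ": organ,
                        "tumor_to_organ": ratio,
                        "tumor_to_organ_display": round(ratio, 1)
                        if math.isfinite(ratio)
                        else ratio,
                    }
                )
        emit("tumor_to_organ_ratios", pd.DataFrame(ratio_rows))

    log = {
        "version": __version__,
        "nuclide": src.name,
        "half_life_h": src.half_life,
        "lambda_p_per_h": src.lambda_p,
        "mean_electron_mev": src.mean_electron_energy,
        "fit_scale": config.fit_scale,
        "decay_corrected_input": config.decay_corrected,
        "mouse_mass_g": config.mouse_mass,
        "muscle_organ": config.muscle_organ,
        "extrapolate_to": config.extrapolate_to,
        "sphere_tissues": list(config.sphere_tissues),
        "seed": config.seed,
    }
    with open(outdir / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=True)
    return outputs
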