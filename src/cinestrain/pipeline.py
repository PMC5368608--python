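"""End-to-end orchestration: geometry -> tracking -> strain -> aggregation.

``analyze_sax_view`` / ``analyze_lax_view`` process one cine slice with its
reference contours into layer and whole-wall peak strains.
``run_analysis`` assembles a subject's StrainRecord (three short-axis
levels plus the four-chamber view) from a config dict / YAML file;
``run_cohort`` runs the cohort simulator and emits the summary, sex,
gradient and age-regression tables.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from cinestrain import io as cio
from cinestrain.aggregate import StrainRecord, records_to_frame
from cinestrain.cohort import CohortSimConfig, simulate_cohort
from cinestrain.core import CineSequence, ContourPair
from cinestrain.geometry import (
    LAYER_NAMES,
    compute_local_directions,
    lax_directions,
    rasterize_myocardium,
)
from cinestrain.phantom import BandContour
from cinestrain.stats import compare_groups, fit_linear_models
from cinestrain.strain import (
    directional_strain_field,
    peak_systolic,
    strain_curves,
)
from cinestrain.tracking import RegistrationParams, track_to_reference

log = logging.getLogger("cinestrain")

SAX_DIRECTIONS = ("Err", "Ecc")


def _strain_maps(cine, fields, geometry, direction):
    return np.stack(
        [directional_strain_field(f, geometry, direction) for f in fields]
    )


def analyze_sax_view(
    cine: CineSequence,
    contours: ContourPair,
    params: RegistrationParams = RegistrationParams(),
    reference: int = 0,
) -> dict:
    """Track one short-axis slice and reduce to peak strains.

    Returns ``{direction: {"layers": {endo/mid/epi: peak}, "wall": peak,
    "curves": [...]}}`` for Err and Ecc.  The "wall" entry is the
    whole-slice mean curve's peak (the slice's contribution to the level
    profile).
    """
    grid = cine.grid
    mask = rasterize_myocardium(contours, grid)
    geometry = compute_local_directions(contours, mask, grid)
    fields = track_to_reference(cine, reference=reference, params=params)
    out = {}
    for direction in SAX_DIRECTIONS:
        maps = _strain_maps(cine, fields, geometry, direction)
        layer_curves = strain_curves(maps, geometry, direction, "layers",
                                     frame_times=cine.frame_times)
        wall_curve = strain_curves(maps, geometry, direction, "global",
                                   frame_times=cine.frame_times)[0]
        out[direction] = {
            "layers": {c.region: peak_systolic(c).value for c in layer_curves},
            "wall": peak_systolic(wall_curve).value,
            "curves": layer_curves + [wall_curve],
        }
    return out


def analyze_lax_view(
    cine: CineSequence,
    band: BandContour,
    params: RegistrationParams = RegistrationParams(),
    reference: int = 0,
) -> dict:
    """Track the four-chamber view and reduce longitudinal strain.

    Returns layer peaks (endo/mid/epi across the wall thickness), level
    peaks (basal/mid/apical thirds of the midline arc length), and the
    whole-wall peak.
    """
    geometry = lax_directions(band.midline, band.thickness, cine.grid)
    fields = track_to_reference(cine, reference=reference, params=params)
    maps = _strain_maps(cine, fields, geometry, "Ell")
    layer_curves = strain_curves(maps, geometry, "Ell", "layers",
                                 frame_times=cine.frame_times)
    level_curves = strain_curves(maps, geometry, "Ell", "levels",
                                 frame_times=cine.frame_times)
    wall_curve = strain_curves(maps, geometry, "Ell", "global",
                               frame_times=cine.frame_times)[0]
    return {
        "layers": {c.region: peak_systolic(c).value for c in layer_curves},
        "levels": {c.region: peak_systolic(c).value for c in level_curves},
        "wall": peak_systolic(wall_curve).value,
        "curves": layer_curves + level_curves + [wall_curve],
    }


def assemble_record(
    sax_results: dict[str, dict],
    lax_result: dict | None,
    subject: str = "",
    sex: str = "",
    age: float = float("nan"),
) -> StrainRecord:
    """Combine per-view results into a StrainRecord.

    ``sax_results`` maps level name ("basal"/"mid"/"apical") to the output
    of ``analyze_sax_view``.  Layer-specific Err/Ecc are the means of the
    per-level layer peaks; level Err/Ecc are the whole-wall slice peaks.
    """
    kwargs: dict = {"subject": subject, "sex": sex, "age": age}
    level_key = {"basal": "basal", "mid": "midlv", "apical": "apical"}
    for direction in SAX_DIRECTIONS:
        for layer in LAYER_NAMES:
            vals = [
                sax_results[lvl][direction]["layers"][layer]
                for lvl in ("basal", "mid", "apical")
                if lvl in sax_results
            ]
            if len(vals) == 3:
                kwargs[f"{direction}_{layer}"] = float(np.mean(vals))
        for lvl, key in level_key.items():
            if lvl in sax_results:
                kwargs[f"{direction}_{key}"] = sax_results[lvl][direction]["wall"]
    if lax_result is not None:
        for layer in LAYER_NAMES:
            kwargs[f"Ell_{layer}"] = lax_result["layers"][layer]
        for lvl, key in level_key.items():
            kwargs[f"Ell_{key}"] = lax_result["levels"][lvl]
    return StrainRecord(**kwargs)


def _load_config(config: dict | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        return yaml.safe_load(Path(config).read_text())
    return dict(config)


def _registration_params(cfg: dict) -> RegistrationParams:
    reg = cfg.get("registration", {})
    fields = {f.name for f in dataclasses.fields(RegistrationParams)}
    unknown = set(reg) - fields
    if unknown:
        raise ValueError(f"unknown registration parameter(s): {', '.join(sorted(unknown))}")
    reg = {k: tuple(v) if isinstance(v, list) else v for k, v in reg.items()}
    return RegistrationParams(**reg)


def run_analysis(config: dict | str | Path, out_dir: str | Path | None = None) -> pd.DataFrame:
    """Run the imaging pipeline for one subject from a config mapping/YAML.

    Config keys: ``subject``, ``sex``, ``age``, ``views`` (list of
    ``{view, cine, contours}`` with view in sax-basal / sax-mid /
    sax-apical / lax-4ch), optional ``registration`` overrides and
    ``output_dir``.  Writes the strain record CSV, per-region curve CSV and
    a reproducibility manifest; any stage failure aborts naming the stage
    and subject.
    """
    cfg = _load_config(config)
    out_dir = Path(out_dir or cfg.get("output_dir", "cinestrain_out"))
    subject = str(cfg.get("subject", "subject"))
    params = _registration_params(cfg)

    sax_results: dict[str, dict] = {}
    lax_result = None
    curves_rows = []
    for entry in cfg.get("views", []):
        view = entry["view"]
        stage = f"view {view} of subject {subject}"
        for key in ("cine", "contours"):
            if not Path(entry[key]).exists():
                raise FileNotFoundError(f"[{stage}] missing input file: {entry[key]}")
        try:
            cine = cio.load_cine(entry["cine"], view=view)
            contours = cio.load_contours(entry["contours"])
            if view.startswith("sax"):
                res = analyze_sax_view(cine, contours, params)
                sax_results[view.split("-", 1)[1]] = res
                curves = [c for d in res.values() for c in d["curves"]]
            elif view.startswith("lax"):
                lax_result = analyze_lax_view(cine, contours, params)
                curves = lax_result["curves"]
            else:
                raise ValueError(f"unknown view tag {view!r}")
        except Exception as exc:
            raise RuntimeError(f"pipeline failed at {stage}: {exc}") from exc
        for c in curves:
            for frame, val in enumerate(c.values):
                curves_rows.append(
                    {"view": view, "direction": c.direction, "region": c.region,
                     "frame": frame, "strain_pct": val}
                )

    record = assemble_record(
        sax_results, lax_result, subject=subject,
        sex=str(cfg.get("sex", "")), age=float(cfg.get("age", np.nan)),
    )
    df = records_to_frame([record])
    out_dir.mkdir(parents=True, exist_ok=True)
    cio.save_table(df, out_dir / "strain_record.csv")
    cio.save_table(pd.DataFrame(curves_rows), out_dir / "strain_curves.csv")
    cio.write_manifest(out_dir, cfg, seeds={"registration": "deterministic"})
    log.info("subject %s analyzed -> %s", subject, out_dir)
    return df


def cohort_tables(df: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Summary tables mirroring a normative-cohort report layout.

    ``summary``: mean +/- SD per direction for layers, levels and global;
    ``by_sex``: the same cells sex-stratified with t-test p-values;
    ``gradients``: the two gradient parameters overall and per sex;
    ``age_regression``: univariable age correlation per layer cell.
    """
    from cinestrain.cohort import CELLS

    def msd(col):
        return f"{df[col].mean():.1f} ± {df[col].std(ddof=1):.1f}"

    rows = []
    for d in ("Err", "Ecc", "Ell"):
        row = {"direction": d}
        for cell in CELLS + ("global",):
            row[cell] = msd(f"{d}_{cell}")
        rows.append(row)
    summary = pd.DataFrame(rows)

    f_df, m_df = df[df.sex == "F"], df[df.sex == "M"]
    rows = []
    for d in ("Err", "Ecc", "Ell"):
        for cell in CELLS:
            col = f"{d}_{cell}"
            res = compare_groups([m_df[col], f_df[col]], design="independent")
            rows.append({
                "direction": d, "cell": cell,
                "male": f"{m_df[col].mean():.1f} ± {m_df[col].std(ddof=1):.1f}",
                "female": f"{f_df[col].mean():.1f} ± {f_df[col].std(ddof=1):.1f}",
                "p_m_vs_f": res.pvalue,
            })
    by_sex = pd.DataFrame(rows)

    rows = []
    for g in ("G_endo_epi", "G_base_apex"):
        res = compare_groups([m_df[g], f_df[g]], design="independent")
        rows.append({
            "parameter": g,
            "total": msd(g),
            "female": f"{f_df[g].mean():.1f} ± {f_df[g].std(ddof=1):.1f}",
            "male": f"{m_df[g].mean():.1f} ± {m_df[g].std(ddof=1):.1f}",
            "p_m_vs_f": res.pvalue,
        })
    gradients = pd.DataFrame(rows)

    rows = []
    for d in ("Err", "Ecc", "Ell"):
        for cell in ("endo", "mid", "epi"):
            fit = fit_linear_models(df, f"{d}_{cell}", ["age"])
            rows.append({
                "direction": d, "layer": cell,
                "r": fit.loc[0, "r"], "slope_per_year": fit.loc[0, "slope"],
                "p": fit.loc[0, "p_uni"],
            })
    age_regression = pd.DataFrame(rows)

    return {"summary": summary, "by_sex": by_sex,
            "gradients": gradients, "age_regression": age_regression}


def run_cohort(
    config: CohortSimConfig | dict | str | Path | None = None,
    out_dir: str | Path = "cohort_out",
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Simulate a cohort and write the full table set plus manifest."""
    if config is None or isinstance(config, CohortSimConfig):
        cfg = config or CohortSimConfig()
    else:
        raw = _load_config(config)
        cfg = CohortSimConfig(**raw)
    df = simulate_cohort(cfg, seed=seed)
    if len(df) < 3:
        raise ValueError(
            f"cohort of n={len(df)} is too small for the statistical tables; need n >= 3"
        )
    tables = cohort_tables(df)
    out_dir = Path(out_dir)
    cio.save_table(df, out_dir / "cohort.csv")
    for name, tab in tables.items():
        cio.save_table(tab, out_dir / f"{name}.csv")
    cio.write_manifest(
        out_dir,
        {"n_total": cfg.n_total, "n_female": cfg.n_female, "rho": cfg.rho,
         "seed": cfg.seed if seed is None else seed},
        seeds={"cohort": cfg.seed if seed is None else seed},
    )
    return {"cohort": df, **tables}
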