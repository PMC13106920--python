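"""End-to-end orchestration: annotations in, tables/models/figures out.

A run takes either an onset CSV or a synthetic-cohort block, and writes
to its output directory:

* the canonical onset table and the derived IOI / ratio / triple /
  bin-count tables;
* per age class, the Poisson peak-significance model: full and null
  fits, likelihood-ratio test, zero-inflation check, within-sex Tukey
  contrasts, and the on-vs-off significance map;
* the regularity table and one beta mixed model per modelled category;
* density curves and peaks per sex x age class for IOIs and ratios;
* a JSON manifest (config, seeds, versions, convergence flags) that
  suffices to reproduce every table bit-identically.

Randomness flows exclusively from the seeds named in the config.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .density_peaks import estimate_density, find_density_peaks
from .glmm_stats import (
    BETA_LOGIT,
    ModelSpec,
    check_zero_inflation,
    detect_significant_categories,
    fit_glmm,
    fit_poisson_glmm,
    likelihood_ratio_test,
    null_spec,
    pairwise_contrasts,
)
from .regularity import prepare_regularity_table
from .rhythm_core import (
    bin_count_table,
    count_bins,
    default_bin_scheme,
    ioi_table,
    ratio_table,
    triples_table,
)
from .song_data import AgeClass, Contribution, Sex, read_onset_table, write_onset_table
from .synthetic_songs import default_class_params, simulate_cohort

log = logging.getLogger("songrhythm.pipeline")


class SyntheticBlock(BaseModel):
    n_individuals: int = 20
    contributions_each: int = 5
    tempo_sd: float = 0.1
    cells: list[str] | None = None  # e.g. ["ADULT:F", "YOUNG_0_2:M"]; None = all


class EstimationBlock(BaseModel):
    n_agq: int = 1  # 1 = Laplace; >1 = adaptive Gauss-Hermite nodes
    maxiter: int = 500
    tol: float = 1e-10


class RunConfig(BaseModel):
    input_csv: str | None = None
    synthetic: SyntheticBlock | None = None
    cap_s: float = Field(5.0, gt=0)
    alpha: float = Field(0.05, gt=0, lt=1)
    seed: int = 0
    regularity_categories: list[str] = ["R12", "R11"]
    regularity_group: str = "contribution_id"
    boundary_transform: bool = True
    estimation: EstimationBlock = EstimationBlock()
    out_dir: str = "songrhythm_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))


def _load_contributions(config: RunConfig) -> list[Contribution]:
    if (config.input_csv is None) == (config.synthetic is None):
        raise ValueError("exactly one of input_csv or synthetic must be given")
    if config.input_csv is not None:
        contributions = read_onset_table(config.input_csv)
        log.info("loaded %d contributions from %s", len(contributions), config.input_csv)
        return contributions
    syn = config.synthetic
    if syn.cells is None:
        param_map = None
    else:
        param_map = {}
        for cell in syn.cells:
            a, s = cell.split(":")
            param_map[(AgeClass[a], Sex(s))] = default_class_params(
                AgeClass[a], Sex(s)
            )
    contributions = simulate_cohort(
        param_map,
        n_individuals=syn.n_individuals,
        contributions_each=syn.contributions_each,
        seed=config.seed,
        tempo_sd=syn.tempo_sd,
        cap=config.cap_s,
    )
    log.info("simulated %d contributions", len(contributions))
    return contributions


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.12g")
    log.info("wrote %s (%d rows)", path.name, len(df))


def _stage(name):
    t0 = time.time()
    log.info("stage %s started", name)
    return lambda: log.info("stage %s done in %.2fs", name, time.time() - t0)


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and return the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scheme = default_bin_scheme()
    manifest: dict = {
        "package_version": __version__,
        "config": json.loads(config.model_dump_json()),
        "scheme_boundaries": [
            [str(b), float(b)] for b in scheme.all_boundaries()
        ],
        "convergence": {},
    }

    done = _stage("load")
    contributions = _load_contributions(config)
    write_onset_table(contributions, out / "onsets.csv")
    done()

    done = _stage("tables")
    iois = ioi_table(contributions, cap=config.cap_s)
    ratios = ratio_table(contributions, scheme, cap=config.cap_s)
    triples = triples_table(contributions, cap=config.cap_s)
    counts = bin_count_table(contributions, scheme, cap=config.cap_s)
    _write(iois, out / "iois.csv")
    _write(ratios, out / "ratios.csv")
    _write(triples, out / "triples.csv")
    _write(counts, out / "bin_counts.csv")
    done()

    # --- peak significance per age class -----------------------------------
    done = _stage("fit-peaks")
    fits = {}
    lrt_rows, zi_rows, contrast_frames, coef_frames = [], [], [], []
    kw = dict(
        n_agq=config.estimation.n_agq,
        maxiter=config.estimation.maxiter,
        tol=config.estimation.tol,
    )
    for age_class in sorted(counts["age_class"].unique()):
        sub = counts[counts["age_class"] == age_class].reset_index(drop=True)
        full = fit_poisson_glmm(sub, **kw)
        null = fit_glmm(sub, null_spec(full.spec), **kw)
        fits[age_class] = (full, null)
        manifest["convergence"][f"poisson_{age_class}"] = {
            "full": full.converged,
            "null": null.converged,
            "sigma2_u": full.sigma2_u,
            "message": full.message,
        }
        lrt = likelihood_ratio_test(full, null)
        lrt_rows.append(
            {
                "age_class": age_class,
                "statistic": lrt.statistic,
                "df": lrt.df,
                "p": lrt.p,
            }
        )
        zi = check_zero_inflation(full)
        zi_rows.append(
            {
                "age_class": age_class,
                "observed_zeros": zi.observed_zeros,
                "expected_zeros": zi.expected_zeros,
                "ratio": zi.ratio,
                "inflated": zi.inflated,
            }
        )
        coefs = full.summary_frame()
        coefs.insert(0, "age_class", age_class)
        coef_frames.append(coefs)
        if not full.degenerate_all_zero:
            by = "sex" if "sex" in full.factor_levels else None
            ct = pairwise_contrasts(full, "bin", by=by)
            ct.insert(0, "age_class", age_class)
            contrast_frames.append(ct)
    _write(pd.DataFrame(lrt_rows), out / "peak_lrt.csv")
    _write(pd.DataFrame(zi_rows), out / "zero_inflation.csv")
    _write(pd.concat(coef_frames, ignore_index=True), out / "peak_model_coefficients.csv")
    if contrast_frames:
        _write(pd.concat(contrast_frames, ignore_index=True), out / "peak_contrasts.csv")
    sig_map = detect_significant_categories(fits, alpha=config.alpha)
    _write(sig_map, out / "significance_map.csv")
    done()

    # --- regularity ---------------------------------------------------------
    done = _stage("regularity")
    bin_count_objs = [
        count_bins(c, scheme, cap=config.cap_s) for c in contributions
    ]
    reg = prepare_regularity_table(
        bin_count_objs,
        scheme,
        categories=config.regularity_categories,
        boundary_transform=config.boundary_transform,
    )
    _write(reg, out / "regularity.csv")
    reg_coef_frames, reg_lrt_rows = [], []
    for cat in config.regularity_categories:
        sub = reg[(reg["category"] == cat) & reg["regularity"].notna()].reset_index(
            drop=True
        )
        if len(sub) < 10:
            log.warning("category %s: only %d regularity rows; model skipped", cat, len(sub))
            continue
        spec = ModelSpec(
            response="regularity",
            factors=("sex", "age_class"),
            interaction=True,
            group=config.regularity_group,
            family=BETA_LOGIT,
        )
        full = fit_glmm(sub, spec, **kw)
        null = fit_glmm(sub, null_spec(spec), **kw)
        manifest["convergence"][f"beta_{cat}"] = {
            "full": full.converged,
            "null": null.converged,
            "sigma2_u": full.sigma2_u,
            "phi": full.phi,
            "message": full.message,
        }
        lrt = likelihood_ratio_test(full, null)
        reg_lrt_rows.append(
            {"category": cat, "statistic": lrt.statistic, "df": lrt.df, "p": lrt.p}
        )
        coefs = full.summary_frame()
        coefs.insert(0, "category", cat)
        reg_coef_frames.append(coefs)
    if reg_coef_frames:
        _write(pd.concat(reg_coef_frames, ignore_index=True), out / "regularity_model_coefficients.csv")
        _write(pd.DataFrame(reg_lrt_rows), out / "regularity_lrt.csv")
    done()

    # --- densities and peaks ------------------------------------------------
    done = _stage("peaks")
    curve_rows, peak_rows = [], []
    for variable, table, col in (("t_k", iois, "t_k"), ("r_k", ratios, "r_k")):
        for (sex, age_class), sub in table.groupby(["sex", "age_class"]):
            vals = sub[col].to_numpy()
            if len(vals) < 2 or np.ptp(vals) == 0:
                log.warning("group %s/%s/%s: too few values for a density", variable, sex, age_class)
                continue
            curve = estimate_density(vals)
            for x, d in zip(curve.grid, curve.density):
                curve_rows.append(
                    {
                        "variable": variable,
                        "sex": sex,
                        "age_class": age_class,
                        "x": x,
                        "density": d,
                        "bandwidth": curve.bandwidth,
                    }
                )
            for rank, pk in enumerate(find_density_peaks(curve)):
                peak_rows.append(
                    {
                        "variable": variable,
                        "sex": sex,
                        "age_class": age_class,
                        "rank": rank,
                        "location": pk.location,
                        "height": pk.height,
                        "prominence": pk.prominence,
                        "n": len(vals),
                    }
                )
    _write(pd.DataFrame(curve_rows), out / "density_curves.csv")
    _write(pd.DataFrame(peak_rows), out / "density_peaks.csv")
    done()

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("run complete: %s", out)
    return out


# ---------------------------------------------------------------------------
# figures


def _ternary_xy(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray):
    """Project simplex proportions to 2-D (p1 left, p3 right, p2 top)."""
    x = p3 + p2 / 2.0
    y = p2 * np.sqrt(3) / 2.0
    return x, y


def render_figures(run_dir: str | Path, formats: Sequence[str] = ("png", "svg")) -> list[Path]:
    """Per sex x age class: IOI density, ratio density with on/off bands, ternary scatter.

    On-integer ranges are shaded lighter than the flanking off-integer
    ranges; the band edges used are also written to
    ``figures/band_edges.json`` for programmatic checks.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    fig_dir = run_dir / "figures"
    fig_dir.mkdir(exist_ok=True)
    curves = pd.read_csv(run_dir / "density_curves.csv")
    triples = pd.read_csv(run_dir / "triples.csv")
    if curves.empty:
        raise FileNotFoundError("density_curves.csv is empty; run the pipeline first")

    scheme = default_bin_scheme()
    band_edges = {}
    for cat in scheme.ranges:
        on_lo, on_hi = scheme.on_range(cat)
        (llo, lhi), (rlo, rhi) = scheme.off_ranges(cat)
        band_edges[cat] = {
            "on": [float(on_lo), float(on_hi)],
            "off_left": [float(llo), float(lhi)],
            "off_right": [float(rlo), float(rhi)],
        }
    with open(fig_dir / "band_edges.json", "w") as fh:
        json.dump(band_edges, fh, indent=2, sort_keys=True)

    written: list[Path] = []
    groups = curves[["sex", "age_class"]].drop_duplicates().itertuples(index=False)
    for sex, age_class in groups:
        stem = f"{sex}_{age_class}"
        # --- IOI density
        sub = curves[
            (curves["variable"] == "t_k")
            & (curves["sex"] == sex)
            & (curves["age_class"] == age_class)
        ]
        if len(sub):
            fig, ax = plt.subplots(figsize=(4, 3))
            ax.plot(sub["x"], sub["density"], color="0.2")
            for ref in (2.0, 4.0):
                ax.axvline(ref, ls="--", color="0.6", lw=0.8)
            ax.set_xlabel("inter-onset interval $t_k$ (s)")
            ax.set_ylabel("density")
            ax.set_title(f"{sex} {age_class}")
            fig.tight_layout()
            for ext in formats:
                p = fig_dir / f"tk_density_{stem}.{ext}"
                fig.savefig(p)
                written.append(p)
            plt.close(fig)
        # --- ratio density with bands
        sub = curves[
            (curves["variable"] == "r_k")
            & (curves["sex"] == sex)
            & (curves["age_class"] == age_class)
        ]
        if len(sub):
            fig, ax = plt.subplots(figsize=(4, 3))
            for cat, bands in band_edges.items():
                ax.axvspan(*bands["on"], color="#74add1", alpha=0.35, lw=0)
                ax.axvspan(*bands["off_left"], color="#4575b4", alpha=0.45, lw=0)
                ax.axvspan(*bands["off_right"], color="#4575b4", alpha=0.45, lw=0)
            ax.plot(sub["x"], sub["density"], color="0.2")
            ax.set_xlabel("rhythmic ratio $r_k$")
            ax.set_ylabel("density")
            ax.set_xlim(0, 1)
            ax.set_title(f"{sex} {age_class}")
            fig.tight_layout()
            for ext in formats:
                p = fig_dir / f"rk_density_{stem}.{ext}"
                fig.savefig(p)
                written.append(p)
            plt.close(fig)
        # --- ternary scatter
        sub = triples[(triples["sex"] == sex) & (triples["age_class"] == age_class)]
        if len(sub):
            fig, ax = plt.subplots(figsize=(4, 3.6))
            x, y = _ternary_xy(
                sub["p1"].to_numpy(), sub["p2"].to_numpy(), sub["p3"].to_numpy()
            )
            tri_x = [0, 1, 0.5, 0]
            tri_y = [0, 0, np.sqrt(3) / 2, 0]
            ax.plot(tri_x, tri_y, color="0.3", lw=0.8)
            ax.scatter(x, y, s=4, alpha=0.4, color="#d73027", edgecolors="none")
            cx, cy = _ternary_xy(
                np.array([1 / 3]), np.array([1 / 3]), np.array([1 / 3])
            )
            ax.plot(cx, cy, "+", color="0.2", ms=8)
            ax.set_aspect("equal")
            ax.axis("off")
            ax.set_title(f"{sex} {age_class}")
            fig.tight_layout()
            for ext in formats:
                p = fig_dir / f"ternary_{stem}.{ext}"
                fig.savefig(p)
                written.append(p)
            plt.close(fig)
        else:
            log.warning("group %s/%s: no triples; ternary panel skipped", sex, age_class)
    return written
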