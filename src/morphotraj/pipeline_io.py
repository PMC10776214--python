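"""Cohort file formats, exclusion accounting, run configuration and the
end-to-end pipeline orchestrator."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import morphotraj
from morphotraj import deformation as deform_mod
from morphotraj import disparity, meshes, relative_pca, trajectories
from morphotraj.shape_core import AlignedCohort, LandmarkConfiguration, align_cohort
from morphotraj.synthetic_data import CohortSpec, SyntheticCohort, make_template, simulate_cohort
from morphotraj.topology import TemplateTopology

log = logging.getLogger("morphotraj")


# ---------------------------------------------------------------------------
# Cohort formats
# ---------------------------------------------------------------------------


def write_cohort(out_dir, cohort: SyntheticCohort) -> dict[str, Path]:
    """Write a cohort as landmarks.csv + metadata.csv, template.obj + pairing.csv.

    Landmark columns are x1,y1,z1,...; exported landmark indices are 1-based.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    L = cohort.topology.n_landmarks
    cols = [f"{ax}{i + 1}" for i in range(L) for ax in ("x", "y", "z")]
    lm = pd.DataFrame(
        [c.coords.ravel() for c in cohort.configs],
        columns=cols,
    )
    lm.insert(0, "id", [c.id for c in cohort.configs])
    meta = pd.DataFrame(
        {
            "id": [c.id for c in cohort.configs],
            "age_y": [c.age for c in cohort.configs],
            "sex": [c.sex for c in cohort.configs],
            "height_cm": [c.height for c in cohort.configs],
            "weight_kg": [c.weight for c in cohort.configs],
        }
    )
    paths = {
        "landmarks": out / "landmarks.csv",
        "metadata": out / "metadata.csv",
        "template": out / "template.obj",
        "pairing": out / "pairing.csv",
    }
    lm.to_csv(paths["landmarks"], index=False)
    meta.to_csv(paths["metadata"], index=False)
    meshes.write_obj(paths["template"], cohort.topology.template_coords, cohort.topology.facets)
    pd.DataFrame(
        {
            "index": np.arange(L) + 1,
            "paired_index": cohort.topology.paired_map + 1,
        }
    ).to_csv(paths["pairing"], index=False)
    return paths


def read_topology(template_obj, pairing_csv) -> TemplateTopology:
    coords, facets = meshes.read_obj(template_obj)
    pairing = pd.read_csv(pairing_csv)
    paired = np.empty(len(coords), dtype=int)
    paired[pairing["index"].to_numpy() - 1] = pairing["paired_index"].to_numpy() - 1
    return TemplateTopology(
        n_landmarks=len(coords), facets=facets, paired_map=paired, template_coords=coords
    )


# ---------------------------------------------------------------------------
# Exclusion accounting
# ---------------------------------------------------------------------------


@dataclass
class ExclusionReport:
    """Sequential per-filter exclusion counts, mirroring a three-step roster audit."""

    initial: int
    counts: dict[str, int]
    retained: int
    excluded_ids: dict[str, list] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"filter": k, "n_excluded": v} for k, v in self.counts.items()]
        rows.append({"filter": "retained", "n_excluded": self.retained})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ExclusionConfig:
    """Configurable roster filters, applied in order.

    1. image/landmark quality: rows whose ``quality_column`` is falsy;
    2. completeness: rows missing (or non-finite) age, sex, height or weight,
       or with non-finite coordinates;
    3. anthropometrics: rows outside explicit bounds per variable, or outside
       the [q, 1-q] quantile band of height, weight and BMI when
       ``quantile`` is set.
    """

    quality_column: str = "quality_ok"
    required: tuple = ("age_y", "sex", "height_cm", "weight_kg")
    bounds: dict | None = None  # e.g. {"height_cm": (50, 210)}
    quantile: float | None = None

    def apply(self, meta: pd.DataFrame, coords: np.ndarray | None = None) -> ExclusionReport:
        """Return the exclusion accounting for a metadata roster."""
        n0 = len(meta)
        keep = pd.Series(True, index=meta.index)
        counts: dict[str, int] = {}
        excluded: dict[str, list] = {}

        # 1. quality
        if self.quality_column in meta.columns:
            bad = keep & ~meta[self.quality_column].astype(bool)
        else:
            bad = pd.Series(False, index=meta.index)
        counts["quality"] = int(bad.sum())
        excluded["quality"] = meta.loc[bad, "id"].tolist() if "id" in meta else []
        keep &= ~bad

        # 2. completeness
        bad = pd.Series(False, index=meta.index)
        for col in self.required:
            if col not in meta.columns:
                bad |= True
                continue
            col_vals = meta[col]
            missing = col_vals.isna()
            if pd.api.types.is_numeric_dtype(col_vals):
                missing |= ~np.isfinite(col_vals.fillna(np.nan).astype(float))
            else:
                missing |= col_vals.astype(str).str.strip().eq("")
            bad |= missing
        if coords is not None:
            bad |= pd.Series(~np.isfinite(coords).all(axis=(1, 2)), index=meta.index)
        bad &= keep
        counts["completeness"] = int(bad.sum())
        excluded["completeness"] = meta.loc[bad, "id"].tolist() if "id" in meta else []
        keep &= ~bad

        # 3. anthropometrics
        bad = pd.Series(False, index=meta.index)
        if self.bounds:
            for col, (lo, hi) in self.bounds.items():
                if col in meta.columns:
                    v = meta[col].astype(float)
                    bad |= (v < lo) | (v > hi)
        if self.quantile is not None:
            q = self.quantile
            sub = meta.loc[keep]
            h = sub["height_cm"].astype(float)
            w = sub["weight_kg"].astype(float)
            bmi = w / (h / 100.0) ** 2
            for v in (h, w, bmi):
                lo, hi = v.quantile(q), v.quantile(1 - q)
                bad |= pd.Series((v < lo) | (v > hi), index=sub.index).reindex(
                    meta.index, fill_value=False
                )
        bad &= keep
        counts["anthropometric"] = int(bad.sum())
        excluded["anthropometric"] = meta.loc[bad, "id"].tolist() if "id" in meta else []
        keep &= ~bad

        return ExclusionReport(
            initial=n0, counts=counts, retained=int(keep.sum()), excluded_ids=excluded
        )


def read_cohort(
    landmarks_csv,
    metadata_csv,
    template_obj=None,
    pairing_csv=None,
    exclusions: ExclusionConfig | None = None,
) -> tuple[list[LandmarkConfiguration], TemplateTopology | None, ExclusionReport]:
    """Read and validate a cohort, applying the configured exclusion filters.

    Raises on duplicate ids or on a landmark-count mismatch with the
    topology files.
    """
    lm = pd.read_csv(landmarks_csv, float_precision="round_trip")
    meta = pd.read_csv(metadata_csv, float_precision="round_trip")
    if lm["id"].duplicated().any() or meta["id"].duplicated().any():
        raise ValueError("duplicate ids in cohort files")
    merged = meta.merge(lm, on="id", how="inner", validate="one_to_one")
    coord_cols = [c for c in lm.columns if c != "id"]
    if len(coord_cols) % 3:
        raise ValueError("landmark CSV must hold x,y,z triples")
    L = len(coord_cols) // 3
    coords = merged[coord_cols].to_numpy(dtype=float).reshape(len(merged), L, 3)

    topology = None
    if template_obj is not None and pairing_csv is not None:
        topology = read_topology(template_obj, pairing_csv)
        if topology.n_landmarks != L:
            raise ValueError(
                f"landmark count {L} does not match topology {topology.n_landmarks}"
            )

    exclusions = exclusions or ExclusionConfig()
    report = exclusions.apply(merged, coords)
    keep = np.ones(len(merged), dtype=bool)
    for ids in report.excluded_ids.values():
        keep &= ~merged["id"].isin(ids).to_numpy()

    configs = [
        LandmarkConfiguration(
            id=str(row.id),
            coords=coords[i],
            age=float(row.age_y),
            sex=str(row.sex),
            height=float(row.height_cm),
            weight=float(row.weight_kg),
        )
        for i, row in enumerate(merged.itertuples())
        if keep[i]
    ]
    return configs, topology, report


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Parameters of an end-to-end analysis run."""

    out_dir: str = "morphotraj_run"
    # either file inputs ...
    landmarks: str | None = None
    metadata: str | None = None
    template: str | None = None
    pairing: str | None = None
    # ... or a simulated cohort
    simulate: bool = True
    n_female: int = 150
    n_male: int = 150
    #: "uniform" keeps the young age groups populated at desk-scale n
    age_distribution: str = "uniform"
    template_resolution: int = 11
    retention: float = 0.99
    sigma_cs: float = 2.25
    sigma_shape: float = 3.0
    grid_step: float = 0.5
    cs_range: tuple = (4.0, 38.0)
    shape_range: tuple = (5.0, 37.0)
    n_perm_dimorphism: int = 200
    variance_range: tuple = (5.0, 37.0)
    variance_bin: float = 1.0
    n_perm_variance: int = 200
    relpca_group_a: tuple = (6.0, 9.0)
    relpca_group_b: tuple = (18.0, 20.0)
    relpca_p: int = 5
    relpca_mode: str = "perm"
    n_perm_relpca: int = 200
    key_ages: tuple = (6.0, 9.0, 12.0, 15.0, 18.0)
    seed: int = 0
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("cs_range", "shape_range", "variance_range", "relpca_group_a",
                    "relpca_group_b", "key_ages"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        cfg = cls(**data)
        lo, hi = cfg.cs_range
        if lo >= hi:
            raise ValueError("cs_range must be increasing")
        lo, hi = cfg.shape_range
        if lo >= hi:
            raise ValueError("shape_range must be increasing")
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _age_group_labels(ages, lo_a, hi_a, lo_b, hi_b):
    labels = np.full(len(ages), "", dtype=object)
    labels[(ages >= lo_a) & (ages <= hi_a)] = "A"
    labels[(ages >= lo_b) & (ages <= hi_b)] = "B"
    return labels


def _write_field(out_dir: Path, name: str, fld, coords) -> None:
    pd.DataFrame(
        {"facet_id": np.arange(len(fld.values)), "area_change_pct": fld.values}
    ).to_csv(out_dir / f"{name}.csv", index=False)
    meshes.write_ply(
        out_dir / f"{name}.ply", coords, fld.topology.facets, fld.values, binary=False
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute align -> trajectories -> dimorphism -> variance -> relative PCA
    -> deformation fields, writing all stage outputs plus a deterministic
    manifest and a markdown summary. Returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    timings: dict[str, float] = {}
    manifest: dict = {
        "package": "morphotraj",
        "version": morphotraj.__version__,
        "config": config.to_dict(),
    }

    def _stage(name):
        log.info("stage %s", name)
        timings[name] = time.time()

    try:
        # -- input ----------------------------------------------------------
        _stage("input")
        if config.simulate:
            topology = make_template(config.template_resolution)
            spec = CohortSpec(
                n_female=config.n_female,
                n_male=config.n_male,
                age_distribution=config.age_distribution,
                seed=config.seed,
            )
            cohort = simulate_cohort(spec, topology)
            configs = cohort.configs
            report = None
        else:
            configs, topology, report = read_cohort(
                config.landmarks, config.metadata, config.template, config.pairing
            )
            if topology is None:
                raise ValueError("template and pairing files are required")
            report.to_frame().to_csv(out / "exclusions.csv", index=False)
            manifest["exclusions"] = report.counts | {"retained": report.retained}
        manifest["n_individuals"] = len(configs)

        # -- alignment ------------------------------------------------------
        _stage("align")
        aligned = align_cohort(configs, topology, retention=config.retention)
        K = aligned.pca.n_components
        manifest["n_components"] = K
        manifest["explained_at_K"] = round(aligned.pca.cumulative_explained, 6)
        score_cols = [f"score_{k + 1}" for k in range(K)]
        tbl = pd.DataFrame(aligned.scores, columns=score_cols)
        tbl.insert(0, "cs_mm", aligned.centroid_sizes)
        tbl.insert(0, "sex", aligned.sexes)
        tbl.insert(0, "age_y", aligned.ages)
        tbl.insert(0, "id", aligned.ids)
        tbl.to_csv(out / "aligned_scores.csv", index=False)
        pd.DataFrame(aligned.pca.eigenvectors).to_csv(out / "eigenbasis_vectors.csv", index=False)
        pd.DataFrame(
            {
                "eigenvalue": aligned.pca.all_eigenvalues,
                "explained_fraction": aligned.pca.all_eigenvalues
                / aligned.pca.all_eigenvalues.sum(),
            }
        ).to_csv(out / "eigenvalues.csv", index=False)
        meshes.write_obj(out / "consensus.obj", aligned.consensus, topology.facets)

        # -- trajectories -----------------------------------------------------
        _stage("trajectories")
        cs_kernel = trajectories.KernelSpec.from_range(
            *config.cs_range, sigma=config.sigma_cs, step=config.grid_step
        )
        shape_kernel = trajectories.KernelSpec.from_range(
            *config.shape_range, sigma=config.sigma_shape, step=config.grid_step
        )
        cs_rows, shape_rows = [], []
        shape_models = {}
        for sex in ("F", "M"):
            sel = aligned.sexes == sex
            cs_model = trajectories.fit_trajectory(
                aligned.centroid_sizes[sel], aligned.ages[sel], cs_kernel, sex=sex
            )
            cs_rows.append(
                pd.DataFrame(
                    {
                        "age_y": cs_model.grid,
                        "sex": sex,
                        "predicted_cs_mm": cs_model.predicted[:, 0],
                        "rate_mm_per_y": cs_model.rates[:, 0],
                        "effective_n": cs_model.effective_n,
                        "valid": cs_model.valid,
                    }
                )
            )
            shape_model = trajectories.fit_trajectory(
                aligned.scores[sel], aligned.ages[sel], shape_kernel, sex=sex
            )
            shape_models[sex] = shape_model
            df = pd.DataFrame(
                {
                    "age_y": shape_model.grid,
                    "sex": sex,
                    "rate_magnitude_per_y": shape_model.rate_magnitudes,
                    "effective_n": shape_model.effective_n,
                    "valid": shape_model.valid,
                }
            )
            for k in range(min(K, 5)):
                df[f"predicted_score_{k + 1}"] = shape_model.predicted[:, k]
            shape_rows.append(df)
        pd.concat(cs_rows).to_csv(out / "trajectory_cs.csv", index=False)
        pd.concat(shape_rows).to_csv(out / "trajectory_shape.csv", index=False)

        # -- dimorphism -------------------------------------------------------
        _stage("dimorphism")
        profile = trajectories.dimorphism_profile(
            aligned.scores,
            aligned.ages,
            aligned.sexes,
            shape_kernel,
            n_perm=config.n_perm_dimorphism,
            seed=config.seed + 1,
        )
        pd.DataFrame(
            {
                "age_y": profile.grid,
                "distance": profile.distance,
                "p_value": profile.p_values,
                "valid": profile.valid,
            }
        ).to_csv(out / "dimorphism.csv", index=False)
        trend = trajectories.smooth_trend(profile.grid, profile.distance)
        pd.DataFrame(
            {
                "age_y": trend.x,
                "fitted": trend.fitted,
                "band_lower": trend.band_lower,
                "band_upper": trend.band_upper,
            }
        ).to_csv(out / "dimorphism_trend.csv", index=False)
        manifest["dimorphism_trend_p"] = trend.p_value
        manifest["dimorphism_seed"] = config.seed + 1

        # -- variance ---------------------------------------------------------
        _stage("variance")
        residuals = disparity.model_residuals(
            aligned.scores, aligned.ages, aligned.sexes, shape_models
        )
        vprof = disparity.variance_profile(
            residuals,
            aligned.ages,
            aligned.sexes,
            lo=config.variance_range[0],
            hi=config.variance_range[1],
            width=config.variance_bin,
            n_perm=config.n_perm_variance,
            seed=config.seed + 2,
        )
        vprof.table.to_csv(out / "variance.csv", index=False)
        if vprof.pairwise_diff is not None:
            vprof.combined_matrix().to_csv(out / "variance_matrix.csv")
        pooled = vprof.table[vprof.table.sex == "pooled"]
        vtrend_p = None
        if len(pooled) >= 10:
            vtrend = disparity.variance_trend(vprof)
            pd.DataFrame(
                {
                    "age_y": vtrend.x,
                    "fitted": vtrend.fitted,
                    "band_lower": vtrend.band_lower,
                    "band_upper": vtrend.band_upper,
                }
            ).to_csv(out / "variance_trend.csv", index=False)
            vtrend_p = vtrend.p_value
        manifest["variance_trend_p"] = vtrend_p
        manifest["variance_seed"] = config.seed + 2

        # -- relative PCA -----------------------------------------------------
        _stage("relative_pca")
        labels = _age_group_labels(
            aligned.ages, *config.relpca_group_a, *config.relpca_group_b
        )
        relpca_result = None
        nA, nB = int((labels == "A").sum()), int((labels == "B").sum())
        if min(nA, nB) > config.relpca_p + 1:
            relpca_result = relative_pca.run_relative_pca(
                aligned.scores,
                labels,
                "A",
                "B",
                p=config.relpca_p,
                mode=config.relpca_mode,
                n_perm=config.n_perm_relpca,
                seed=config.seed + 3,
            )
            pd.DataFrame(
                {
                    "component": np.arange(config.relpca_p) + 1,
                    "relative_eigenvalue": relpca_result.eigenvalues,
                }
            ).to_csv(out / "relpca_eigenvalues.csv", index=False)
            relpca_result.successive.to_csv(out / "relpca_tests.csv", index=False)
            manifest["relpca"] = {
                "generalized_variance_ratio_pct": 100.0
                * relpca_result.generalized_variance_ratio,
                "proportionality_p": relpca_result.proportionality.p_value,
                "n_group_a": relpca_result.n1,
                "n_group_b": relpca_result.n2,
            }
            # most extreme relative eigenvector -> feature deformation
            j = int(np.argmax(np.abs(np.log(relpca_result.eigenvalues))))
            src, tgt = relative_pca.relative_feature_shape(
                relpca_result.eigenvectors[:, j],
                relpca_result.subspace_basis,
                aligned.pca.eigenvectors,
                aligned.consensus,
                amplitude=2.0 * np.sqrt(aligned.pca.eigenvalues[0]),
            )
            fld = deform_mod.deformation_field(src, tgt, topology)
            _write_field(out, "relpca_feature_field", fld, src)
        else:
            manifest["relpca"] = None
            log.warning("relative PCA skipped: group sizes %d/%d too small", nA, nB)
        manifest["relpca_seed"] = config.seed + 3

        # -- deformation fields ----------------------------------------------
        _stage("deformation")
        basis = aligned.pca.eigenvectors
        consensus = aligned.consensus
        correlations = []
        for age in config.key_ages:
            if not (shape_kernel.grid[0] <= age <= shape_kernel.grid[-1]):
                continue
            gi = int(np.argmin(np.abs(shape_kernel.grid - age)))
            fields = {}
            for sex in ("F", "M"):
                m = shape_models[sex]
                fld = deform_mod.rate_effect_field(
                    m.predicted[gi], m.rates[gi], basis, consensus, topology, step=1.0
                )
                fields[sex] = fld
                _write_field(
                    out, f"rate_field_{sex}_age{age:g}", fld,
                    deform_mod.scores_to_shape(m.predicted[gi], basis, consensus),
                )
            dfld = deform_mod.dimorphism_field(
                shape_models["F"].predicted[gi],
                shape_models["M"].predicted[gi],
                basis,
                consensus,
                topology,
            )
            _write_field(
                out, f"dimorphism_field_age{age:g}", dfld,
                deform_mod.scores_to_shape(shape_models["F"].predicted[gi], basis, consensus),
            )
            correlations.append(
                {
                    "age_y": age,
                    "pearson_r_FM_rate_fields": deform_mod.field_correlation(
                        fields["F"], fields["M"]
                    ),
                }
            )
        pd.DataFrame(correlations).to_csv(out / "field_correlations.csv", index=False)

        # -- report -----------------------------------------------------------
        _stage("report")
        manifest["stages"] = list(timings)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        _write_report(out, manifest)
        if config.make_plots:
            _write_plots(out)
    except Exception as err:
        stage = list(timings)[-1] if timings else "input"
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err

    elapsed = {k: round(time.time() - v, 3) for k, v in timings.items()}
    (out / "run.log").write_text(
        "\n".join(f"{k}: started at +{round(v - t_start, 3)}s" for k, v in timings.items())
        + f"\ntotal: {round(time.time() - t_start, 3)}s\n"
    )
    log.info("pipeline complete in %.1fs (%s)", time.time() - t_start, elapsed)
    return manifest


def _write_report(out: Path, manifest: dict) -> None:
    lines = [
        "# morphotraj run summary",
        "",
        f"- package version: {manifest['version']}",
        f"- individuals analysed: {manifest['n_individuals']}",
        f"- retained eigenbasis: {manifest['n_components']} components "
        f"({100 * manifest['explained_at_K']:.1f}% of symmetric shape variance)",
        f"- dimorphism trend (smooth p): {manifest['dimorphism_trend_p']:.4g}",
        f"- Procrustes-variance trend (smooth p): {manifest['variance_trend_p']}",
    ]
    if manifest.get("relpca"):
        r = manifest["relpca"]
        lines += [
            f"- generalized variance ratio (group A / group B): "
            f"{r['generalized_variance_ratio_pct']:.1f}%",
            f"- proportionality test p: {r['proportionality_p']:.4g} "
            f"(n = {r['n_group_a']}/{r['n_group_b']})",
        ]
    if "exclusions" in manifest:
        ex = manifest["exclusions"]
        lines.append(f"- exclusion accounting: {ex}")
    lines += [
        "",
        "Artifacts: aligned_scores.csv, eigenvalues.csv, trajectory_cs.csv,",
        "trajectory_shape.csv, dimorphism.csv (+trend), variance.csv (+matrix,",
        "trend), relpca_eigenvalues.csv, relpca_tests.csv, per-age deformation",
        "fields (CSV + ascii PLY with per-face `area_change_pct`).",
        "",
        "Units: ages in years (age_y), centroid size in mm (cs_mm), deformation",
        "fields in percent area change; shape scores and Procrustes distances",
        "are dimensionless (unit-centroid-size frame).",
    ]
    (out / "report.md").write_text("\n".join(lines) + "\n")


def _write_plots(out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    specs = [
        ("trajectory_cs.csv", "age_y", "predicted_cs_mm", "sex", "cs_trajectory.png"),
        ("trajectory_shape.csv", "age_y", "rate_magnitude_per_y", "sex", "shape_rate.png"),
        ("dimorphism.csv", "age_y", "distance", None, "dimorphism.png"),
        ("variance.csv", "bin", "variance", "sex", "variance.png"),
    ]
    for fname, xcol, ycol, hue, png in specs:
        path = out / fname
        if not path.exists():
            continue
        df = pd.read_csv(path)
        fig, ax = plt.subplots(figsize=(6, 4))
        if hue:
            for key, sub in df.groupby(hue):
                ax.plot(sub[xcol], sub[ycol], label=str(key))
            ax.legend()
        else:
            ax.plot(df[xcol], df[ycol])
        ax.set_xlabel(xcol)
        ax.set_ylabel(ycol)
        fig.tight_layout()
        fig.savefig(out / png, dpi=100)
        plt.close(fig)
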