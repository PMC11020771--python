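"""End-to-end orchestration: shape → levers → FEA → phylogenetic statistics.

A run takes either a synthetic-study parameter block or real input files
(TPS landmarks, lever CSV, mesh CSV pairs, muscle-attachment CSV, Newick
tree), executes

1. generalized Procrustes superimposition, shape PCA, centroid sizes and
   boxplot outlier tests,
2. jaw-closing mechanical advantage per muscle group and ΔMA,
3. plane-strain bite models with constant-stress load scaling (reference
   force on the smallest model), MWAM strain, the intervals method, and
   fenestra/surface-area ratios,
4. phylogenetic signal (K_mult on shape, MA and intervals data; Blomberg's
   K per shape PC) and a PGLS battery (each PC, centroid size, fenestra
   ratios and skull length against the functional metrics),

and writes one CSV table per result family plus a run log.  Defaults match
the standard bite-model parametrisation: E = 20.49 GPa, ν = 0.4, reference
force 30 N, equal temporal/quadrate force split, four strain intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fea_planar as fea
from . import lever_mechanics as lever
from . import morphometrics as morpho
from . import phylo_pcm as pcm
from . import shape_data
from . import synthetic_data as synth

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """An analysis stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Validated, defaults-filled pipeline configuration."""

    # exactly one of the two input modes
    synthetic: dict | None = None
    inputs: dict | None = None
    # FEA block
    young_modulus_mpa: float = 20490.0
    poisson_ratio: float = 0.4
    reference_force_n: float = 30.0
    temporal_fraction: float = 0.5
    n_intervals: int = 4
    upper_bound_micro: float = 250.0
    traction_lumping: str = "tributary"
    # PCM block
    n_perm: int = 999
    include_outgroup: bool = True
    # general
    seed: int = 0
    output_dir: str | None = None
    quartile_method: str = "linear"


_FEA_KEYS = {"young_modulus_mpa", "poisson_ratio", "reference_force_n",
             "temporal_fraction", "n_intervals", "upper_bound_micro",
             "traction_lumping"}
_PCM_KEYS = {"n_perm", "include_outgroup"}
_SYNTH_KEYS = {"n_taxa", "tree_seed", "mode_rates", "noise_sd", "variant",
               "skull_length_mm", "fenestra_fraction", "target_edge_mm"}
_INPUT_KEYS = {"tps", "levers", "tree", "meshes", "attachments"}
_TOP_KEYS = {"synthetic", "inputs", "fea", "pcm", "seed", "output_dir",
             "quartile_method"}


def validate_config(config) -> RunConfig:
    """Normalise a config dict (or YAML path) into a :class:`RunConfig`.

    Fills documented defaults, rejects unknown keys and contradictory
    settings (both or neither input mode, negative reference force, ...).
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if config is None:
        config = {}
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping")
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    synthetic = config.get("synthetic")
    inputs = config.get("inputs")
    if (synthetic is None) == (inputs is None):
        raise ValueError("exactly one of 'synthetic' or 'inputs' must be given")
    if synthetic is not None:
        bad = set(synthetic) - _SYNTH_KEYS
        if bad:
            raise ValueError(f"unknown synthetic key(s): {sorted(bad)}")
    if inputs is not None:
        bad = set(inputs) - _INPUT_KEYS
        if bad:
            raise ValueError(f"unknown inputs key(s): {sorted(bad)}")
        for key in ("tps", "levers", "tree"):
            if key not in inputs:
                raise ValueError(f"inputs block missing {key!r}")
            if not Path(inputs[key]).exists():
                raise ValueError(f"input file does not exist: {inputs[key]}")
    cfg = RunConfig(synthetic=synthetic, inputs=inputs)
    for block, keys in (("fea", _FEA_KEYS), ("pcm", _PCM_KEYS)):
        sub = config.get(block) or {}
        bad = set(sub) - keys
        if bad:
            raise ValueError(f"unknown {block} key(s): {sorted(bad)}")
        for k, v in sub.items():
            setattr(cfg, k, v)
    for k in ("seed", "output_dir", "quartile_method"):
        if k in config:
            setattr(cfg, k, config[k])
    if cfg.reference_force_n <= 0:
        raise ValueError("reference_force_n must be positive")
    if not (0.0 <= cfg.temporal_fraction <= 1.0):
        raise ValueError("temporal_fraction must lie in [0, 1]")
    if cfg.n_intervals < 2:
        raise ValueError("n_intervals must be at least 2")
    if cfg.upper_bound_micro <= 0:
        raise ValueError("upper_bound_micro must be positive")
    # validate material eagerly so errors surface at config time
    fea.Material(cfg.young_modulus_mpa, cfg.poisson_ratio)
    return cfg


# ---------------------------------------------------------------------------
# FEA load-case construction
# ---------------------------------------------------------------------------

def build_bite_case(mesh: fea.PlanarMesh, lever_set: lever.LeverSet,
                    attachments: dict, total_force: float,
                    temporal_fraction: float = 0.5) -> fea.LoadCase:
    """Anterior-bite load case: bite node fixed dorsoventrally, jaw joint
    fixed fully; muscle loads split between the temporal and quadrate
    groups, divided equally within a group's attachment nodes, each
    directed from its node toward the group's insertion target.

    Per-node force magnitudes within the groups sum to ``total_force``.
    """
    bite_node = mesh.nearest_node(lever_set.anterior_bite_point)
    joint_node = mesh.nearest_node(lever_set.jaw_joint)
    constraints = [(bite_node, frozenset({"y"})),
                   (joint_node, frozenset({"x", "y"}))]
    shares = {"temporal": temporal_fraction, "quadrate": 1.0 - temporal_fraction}
    targets = {"temporal": np.asarray(lever_set.temporal_insertion, dtype=float),
               "quadrate": np.asarray(lever_set.quadrate_insertion, dtype=float)}
    loads: list[tuple[int, np.ndarray]] = []
    meta: dict = {}
    for group, (centre, radius) in attachments.items():
        share = shares.get(group)
        if share is None:
            raise ValueError(f"unknown muscle group {group!r}")
        if share == 0.0:
            continue
        d = np.linalg.norm(mesh.nodes - np.asarray(centre, dtype=float), axis=1)
        node_ids = np.flatnonzero(d <= radius)
        if len(node_ids) == 0:
            node_ids = np.array([int(np.argmin(d))])
        per_node = share * total_force / len(node_ids)
        for nid in node_ids:
            direction = targets[group] - mesh.nodes[nid]
            norm = np.linalg.norm(direction)
            if norm == 0:
                continue
            loads.append((int(nid), per_node * direction / norm))
        meta[group] = {"nodes": node_ids.tolist(), "share": share,
                       "target": targets[group].tolist()}
    return fea.LoadCase(constraints=constraints, loads=loads, muscle_groups=meta)


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------

@dataclass
class ReportBundle:
    """All pipeline result tables plus the run log."""

    variant_summary: pd.DataFrame
    variance_table: pd.DataFrame
    scores_table: pd.DataFrame
    centroid_size_table: pd.DataFrame
    outlier_table: pd.DataFrame
    ma_fea_summary: pd.DataFrame
    intervals_table: pd.DataFrame
    pca_and_signal: pd.DataFrame
    pgls_table: pd.DataFrame
    run_log: list[str] = field(default_factory=list)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {f.name: getattr(self, f.name) for f in fields(self)
                if f.name != "run_log"}

    def validate(self) -> None:
        for name, df in self.tables().items():
            if df.columns.empty:
                raise ValueError(f"table {name} has no header")
        vcols = [c for c in self.intervals_table.columns if c.startswith("V")]
        if len(self.intervals_table):
            sums = self.intervals_table[vcols].sum(axis=1)
            if (sums - 100.0).abs().max() > 1e-6:
                raise ValueError("interval rows do not sum to 100")
        mfs = self.ma_fea_summary
        if len(mfs):
            delta = mfs["quadrate_ma"] - mfs["temporal_ma"]
            if not np.array_equal(delta.to_numpy(), mfs["delta_ma"].to_numpy()):
                raise ValueError("delta_ma column inconsistent")

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables().items():
            df.to_csv(outdir / f"{name}.csv", index=False, float_format="%.12g")
        (outdir / "run_log.txt").write_text("\n".join(self.run_log) + "\n")


def expected_pgls_count(n_pcs: int, n_fenestra_types: int) -> int:
    """Number of PGLS models the report battery fits.

    Per PC: temporal MA, quadrate MA and MWAM (3 each); centroid size
    against the same three; total and per-type fenestra ratios against both
    MA metrics; skull length vs MWAM plain and log-log.
    """
    return n_pcs * 3 + 3 + (1 + n_fenestra_types) * 2 + 2


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _load_inputs(cfg: RunConfig):
    """Assemble a study-like object from real input files."""
    inputs = cfg.inputs
    configs = shape_data.read_tps(inputs["tps"])
    levers = {lv.taxon_id: lv for lv in lever.read_lever_csv(inputs["levers"])}
    tree = pcm.read_newick(inputs["tree"])
    meshes = {}
    for taxon, pair in (inputs.get("meshes") or {}).items():
        meshes[taxon] = fea.read_mesh_csv(pair["nodes"], pair["elements"])
    attachments: dict[str, dict] = {}
    if inputs.get("attachments"):
        df = pd.read_csv(inputs["attachments"])
        for _, row in df.iterrows():
            attachments.setdefault(row["taxon_id"], {})[row["group"]] = (
                np.array([row["cx_mm"], row["cy_mm"]]), float(row["radius_mm"]))
    n = len(configs[0].points)
    variant = shape_data.DatasetVariantSpec("custom", n, 0, 0,
                                            [c.taxon_id for c in configs])
    dataset = shape_data.ShapeDataset(variant=variant, configurations=configs)
    dataset.validate(require_pca=True)
    return dataset, levers, tree, meshes, attachments


def run_pipeline(config) -> ReportBundle:
    """Execute the full analysis described by ``config``; see module docs."""
    cfg = config if isinstance(config, RunConfig) else validate_config(config)
    log: list[str] = [f"seed={cfg.seed}"]
    rng = np.random.default_rng(cfg.seed)

    # --- stage: data acquisition -------------------------------------------
    try:
        if cfg.synthetic is not None:
            params = dict(cfg.synthetic)
            params.setdefault("seed", cfg.seed)
            study = synth.generate_study(**params)
            dataset, levers, tree = study.dataset, study.levers, study.tree
            meshes = study.meshes
            attachments = {t: g.attachments for t, g in study.geometries.items()}
            log.append(f"synthetic study: n_taxa={len(study.taxa)} "
                       f"variant={dataset.variant.variant_id}")
        else:
            dataset, levers, tree, meshes, attachments = _load_inputs(cfg)
            log.append(f"loaded inputs: {len(dataset.configurations)} configurations")
    except Exception as exc:
        raise PipelineStageError("data", exc) from exc

    taxa = [c.taxon_id for c in dataset.configurations]

    # --- stage: morphometrics ----------------------------------------------
    try:
        aligned = morpho.gpa(dataset)
        pca = morpho.pca_shapes(aligned)
        n_pcs = int(np.sum(pca.variance_fraction > 1e-12))
        sizes = pd.Series(aligned.centroid_sizes, index=taxa, name="centroid_size_mm")
        lengths = pd.Series({t: synth.skull_length(c)
                             for t, c in zip(taxa, dataset.configurations)},
                            name="skull_length_mm")
        scores = pd.DataFrame(pca.scores[:, :n_pcs], index=taxa,
                              columns=[f"PC{i + 1}" for i in range(n_pcs)])
        outlier_rows = []
        for j in range(n_pcs):
            rep = morpho.boxplot_outliers(scores[f"PC{j + 1}"],
                                          variable_id=f"PC{j + 1}",
                                          quartile_method=cfg.quartile_method)
            outlier_rows.extend(
                {"variable": rep.variable_id, "specimen_id": s, "value": v,
                 "side": side, "lower_fence": rep.lower_fence,
                 "upper_fence": rep.upper_fence}
                for s, v, side in rep.outliers)
        rep = morpho.boxplot_outliers(sizes, variable_id="centroid_size",
                                      quartile_method=cfg.quartile_method)
        outlier_rows.extend(
            {"variable": rep.variable_id, "specimen_id": s, "value": v,
             "side": side, "lower_fence": rep.lower_fence,
             "upper_fence": rep.upper_fence}
            for s, v, side in rep.outliers)
        log.append(f"GPA converged in {aligned.iterations_used} iterations; "
                   f"{n_pcs} non-trivial PCs")
    except Exception as exc:
        raise PipelineStageError("morphometrics", exc) from exc

    # --- stage: mechanical advantage ---------------------------------------
    try:
        ma = lever.ma_table([levers[t] for t in taxa])
        ma = ma.set_index("taxon_id")
        log.append("MA computed for all taxa")
    except Exception as exc:
        raise PipelineStageError("lever_mechanics", exc) from exc

    # --- stage: FEA ---------------------------------------------------------
    fea_rows, interval_rows = [], []
    try:
        material = fea.Material(cfg.young_modulus_mpa, cfg.poisson_ratio)
        if meshes:
            areas = {t: m.solid_area for t, m in meshes.items()}
            ref_area = min(areas.values())
            for t in taxa:
                if t not in meshes:
                    continue
                mesh = meshes[t]
                force = fea.scale_force(cfg.reference_force_n, ref_area, areas[t])
                case = build_bite_case(mesh, levers[t], attachments[t], force,
                                       cfg.temporal_fraction)
                result = fea.solve_case(mesh, material, case,
                                        n_intervals=cfg.n_intervals,
                                        upper_bound_micro=cfg.upper_bound_micro)
                result.validate()
                ratios = (fea.fenestra_ratios(mesh) if mesh.fenestra_polygons
                          else {})
                fea_rows.append({
                    "taxon_id": t, "mwam_strain_micro": result.mwam_strain,
                    "fenestra_ratio": result.fenestra_ratio,
                    "applied_force_n": force,
                    **{f"ratio_{k}": v for k, v in ratios.items()}})
                interval_rows.append({
                    "taxon_id": t,
                    **{f"V{i + 1}": p for i, p in enumerate(result.intervals)}})
            log.append(f"FEA solved for {len(fea_rows)} taxa "
                       f"(reference area {ref_area:.6g} mm^2)")
        else:
            log.append("no meshes provided; FEA stage skipped")
    except Exception as exc:
        raise PipelineStageError("fea_planar", exc) from exc

    fea_df = pd.DataFrame(
        fea_rows, columns=["taxon_id", "mwam_strain_micro", "fenestra_ratio",
                           "applied_force_n"] if not fea_rows else None)
    if len(fea_df):
        fea_df = fea_df.set_index("taxon_id")
    intervals_df = pd.DataFrame(interval_rows)

    # --- stage: phylogenetic comparative methods ---------------------------
    try:
        flat = pd.DataFrame(
            aligned.aligned_points.reshape(len(taxa), -1), index=taxa)
        signal_rows = []
        seed_shape = int(rng.integers(2 ** 31 - 1))
        k_shape = pcm.kmult(tree, flat, n_perm=cfg.n_perm, seed=seed_shape)
        signal_rows.append({"variable": "shape (K_mult)",
                            "statistic": k_shape.statistic,
                            "p_value": k_shape.p_value})
        k_ma = pcm.kmult(tree, ma[["temporal_ma", "quadrate_ma"]],
                         n_perm=cfg.n_perm, seed=int(rng.integers(2 ** 31 - 1)))
        signal_rows.append({"variable": "MA (K_mult)",
                            "statistic": k_ma.statistic, "p_value": k_ma.p_value})
        if len(intervals_df):
            iv = intervals_df.set_index("taxon_id")
            if iv.to_numpy().std(axis=0).sum() > 0:
                k_iv = pcm.kmult(tree, iv, n_perm=cfg.n_perm,
                                 seed=int(rng.integers(2 ** 31 - 1)))
                signal_rows.append({"variable": "intervals (K_mult)",
                                    "statistic": k_iv.statistic,
                                    "p_value": k_iv.p_value})
        for j in range(n_pcs):
            k_pc = pcm.blomberg_k(tree, scores[f"PC{j + 1}"], n_perm=cfg.n_perm,
                                  seed=int(rng.integers(2 ** 31 - 1)))
            signal_rows.append({"variable": f"PC{j + 1} (K)",
                                "statistic": k_pc.statistic,
                                "p_value": k_pc.p_value})
        signal_df = pd.DataFrame(signal_rows,
                                 columns=["variable", "statistic", "p_value"])

        # PGLS battery
        responses = {"temporal_ma": ma["temporal_ma"],
                     "quadrate_ma": ma["quadrate_ma"]}
        if len(fea_df):
            responses["mwam"] = fea_df["mwam_strain_micro"]
        pgls_rows = []

        def _fit(term, resp, pred):
            try:
                f = pcm.pgls(tree, resp, pred)
                pgls_rows.append({"term": term, "slope": f.slope,
                                  "p_value": f.slope_p,
                                  "pseudo_r2_adj": f.pseudo_r2_adj, "n": f.n})
            except ValueError as e:
                pgls_rows.append({"term": term, "slope": np.nan,
                                  "p_value": np.nan, "pseudo_r2_adj": np.nan,
                                  "n": len(resp)})
                log.append(f"PGLS {term}: skipped ({e})")

        mwam_series = (fea_df["mwam_strain_micro"] if len(fea_df)
                       else pd.Series(np.nan, index=taxa))
        for j in range(n_pcs):
            pc = scores[f"PC{j + 1}"]
            _fit(f"temporal_ma ~ PC{j + 1}", ma["temporal_ma"], pc)
            _fit(f"quadrate_ma ~ PC{j + 1}", ma["quadrate_ma"], pc)
            _fit(f"mwam ~ PC{j + 1}", mwam_series, pc)
        _fit("temporal_ma ~ centroid_size", ma["temporal_ma"], sizes)
        _fit("quadrate_ma ~ centroid_size", ma["quadrate_ma"], sizes)
        _fit("mwam ~ centroid_size", mwam_series, sizes)
        ratio_cols = {}
        if len(fea_df):
            ratio_cols["fenestra_total"] = fea_df["fenestra_ratio"]
            for col in fea_df.columns:
                if col.startswith("ratio_"):
                    ratio_cols[col.replace("ratio_", "fenestra_")] = fea_df[col]
        for name, series in ratio_cols.items():
            _fit(f"temporal_ma ~ {name}", ma["temporal_ma"], series)
            _fit(f"quadrate_ma ~ {name}", ma["quadrate_ma"], series)
        _fit("mwam ~ skull_length", mwam_series, lengths)
        if len(fea_df) and (mwam_series > 0).all():
            _fit("log_mwam ~ log_skull_length", np.log(mwam_series),
                 np.log(lengths))
        else:
            _fit("log_mwam ~ log_skull_length", mwam_series, lengths)
        pgls_df = pd.DataFrame(pgls_rows,
                               columns=["term", "slope", "p_value",
                                        "pseudo_r2_adj", "n"])
        log.append(f"PCM: {len(signal_rows)} signal tests, "
                   f"{len(pgls_rows)} PGLS fits (n_perm={cfg.n_perm})")
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("phylo_pcm", exc) from exc

    # --- report assembly ----------------------------------------------------
    variant = dataset.variant
    variant_summary = pd.DataFrame([{
        "variant_id": variant.variant_id,
        "n_specimens": len(dataset.configurations),
        "n_traditional": variant.n_traditional,
        "n_curves": variant.n_curves,
        "points_per_curve": variant.points_per_curve,
        "n_semilandmarks": variant.n_curves * variant.points_per_curve,
        "total_landmarks": variant.total,
    }])
    variance_table = pd.DataFrame({
        "component": [f"PC{i + 1}" for i in range(n_pcs)],
        "eigenvalue": pca.eigenvalues[:n_pcs],
        "variance_fraction": pca.variance_fraction[:n_pcs],
    })
    centroid_table = pd.DataFrame({
        "specimen_id": aligned.specimen_ids or taxa,
        "taxon_id": taxa,
        "centroid_size_mm": aligned.centroid_sizes,
        "skull_length_mm": lengths.to_numpy(),
    })
    ma_fea = ma.copy()
    if len(fea_df):
        ma_fea = ma_fea.join(fea_df)
    ma_fea = ma_fea.reset_index()
    bundle = ReportBundle(
        variant_summary=variant_summary,
        variance_table=variance_table,
        scores_table=scores.reset_index(names="taxon_id"),
        centroid_size_table=centroid_table,
        outlier_table=pd.DataFrame(
            outlier_rows, columns=["variable", "specimen_id", "value", "side",
                                   "lower_fence", "upper_fence"]),
        ma_fea_summary=ma_fea,
        intervals_table=intervals_df,
        pca_and_signal=signal_df,
        pgls_table=pgls_df,
        run_log=log,
    )
    bundle.validate()
    if cfg.output_dir:
        bundle.write(cfg.output_dir)
        logger.info("report written to %s", cfg.output_dir)
    return bundle


# ---------------------------------------------------------------------------
# Fixture bundles (written by the `simulate` CLI verb, readable via inputs:)
# ---------------------------------------------------------------------------

def write_study_bundle(study: synth.SyntheticStudy, outdir) -> dict:
    """Write a synthetic study as the file formats the pipeline reads.

    Returns the ``inputs:`` mapping pointing at the written files.
    """
    outdir = Path(outdir)
    (outdir / "meshes").mkdir(parents=True, exist_ok=True)
    tps = outdir / "landmarks.tps"
    shape_data.write_tps(study.dataset.configurations, tps)
    levers_csv = outdir / "levers.csv"
    lever.write_lever_csv([study.levers[t] for t in study.taxa], levers_csv)
    tree_path = outdir / "tree.nwk"
    pcm.write_newick(study.tree, tree_path)
    mesh_map = {}
    for taxon, mesh in study.meshes.items():
        np_ = outdir / "meshes" / f"{taxon}_nodes.csv"
        ep = outdir / "meshes" / f"{taxon}_elements.csv"
        fea.write_mesh_csv(mesh, np_, ep)
        mesh_map[taxon] = {"nodes": str(np_), "elements": str(ep)}
    rows = []
    for taxon, geom in study.geometries.items():
        for group, (centre, radius) in geom.attachments.items():
            rows.append({"taxon_id": taxon, "group": group,
                         "cx_mm": centre[0], "cy_mm": centre[1],
                         "radius_mm": radius})
    att = outdir / "attachments.csv"
    pd.DataFrame(rows).to_csv(att, index=False, float_format="%.12g")
    study.true_mode_weights.to_csv(outdir / "true_mode_weights.csv",
                                   float_format="%.12g")
    return {"tps": str(tps), "levers": str(levers_csv),
            "tree": str(tree_path), "meshes": mesh_map,
            "attachments": str(att)}
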