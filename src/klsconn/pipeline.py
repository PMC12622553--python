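"""End-to-end pipeline: simulate -> similarity -> nodal stats -> PLS -> covnet.

The human arm generates a two-group PET cohort, builds per-subject KLS
connectomes, compares covariate-adjusted nodal strength between groups, then
uses the resulting t-map as the target for a synthetic gene-expression matrix
and runs the PLS imaging-transcriptomics analysis.  The rodent arm generates
two SUV cohorts and runs the permutation-thresholded covariance-network
comparison.  Every artifact is stamped with the config hash; rerunning with
an identical config reproduces identical files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import covnet, io, netstats, similarity, simulate, transcriptomics
from .config import RunConfig
from .exceptions import KlsconnError, StageError

__all__ = ["run_pipeline"]


def _human_spec(config: RunConfig) -> simulate.HumanCohortSpec:
    d = dict(config.human)
    d.setdefault("n_cases", 10)
    d.setdefault("n_controls", 10)
    d.setdefault("n_roi", 30)
    d.setdefault("voxels_per_roi", 100)
    if "effect_rois" in d:
        d["effect_rois"] = frozenset(d["effect_rois"])
    d.setdefault("seed", config.stage_seed("human"))
    return simulate.HumanCohortSpec(**d)


def _gene_spec(config: RunConfig, n_regions: int) -> simulate.GeneMatrixSpec:
    d = dict(config.gene)
    d.setdefault("n_regions", n_regions)
    d.setdefault("n_genes", 500)
    d.setdefault("n_planted_pos", 10)
    d.setdefault("n_planted_neg", 10)
    d.setdefault("seed", config.stage_seed("gene"))
    return simulate.GeneMatrixSpec(**d)


def _mouse_spec(config: RunConfig) -> simulate.MouseCohortSpec:
    d = dict(config.mouse)
    if "block_structure" in d:
        bs = d["block_structure"]
        if isinstance(bs, dict):
            d["block_structure"] = {
                g: tuple((tuple(r), float(rho)) for r, rho in blocks)
                for g, blocks in bs.items()
            }
        else:
            d["block_structure"] = tuple((tuple(r), float(rho)) for r, rho in bs)
    if "group_names" in d:
        d["group_names"] = tuple(d["group_names"])
    d.setdefault("seed", config.stage_seed("mouse"))
    return simulate.MouseCohortSpec(**d)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all stages; return the manifest written to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.config_hash, "artifacts": [], "stages": {}}

    def record(path: Path) -> None:
        manifest["artifacts"].append(str(path.relative_to(out)))

    def fail(stage: str, exc: Exception):
        manifest["stages"][stage] = "failed"
        io.write_json_summary(manifest, out / "manifest.json")
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    # ---- stage: simulate (human) -------------------------------------
    stage = "simulate_human"
    try:
        hspec = _human_spec(config)
        subjects, design = simulate.generate_human_cohort(hspec)
        io.write_design(design, out / "design.tsv")
        io.write_sidecar(out / "design.tsv", hspec, seed=hspec.seed)
        record(out / "design.tsv")
        manifest["stages"][stage] = "ok"
    except KlsconnError as exc:
        fail(stage, exc)

    # ---- stage: similarity -------------------------------------------
    stage = "similarity"
    try:
        strengths = []
        strength_rows = []
        for subj in subjects:
            m = similarity.build_similarity_matrix(
                subj.samples,
                n_grid=config.n_grid,
                bandwidth_method=config.bandwidth_method,
                epsilon=config.epsilon,
            )
            m.meta["config_hash"] = config.config_hash
            sv = netstats.nodal_strength(m)
            strengths.append(sv)
            strength_rows.append(sv.strength)
        first = subjects[0]
        mat0 = similarity.build_similarity_matrix(
            first.samples,
            n_grid=config.n_grid,
            bandwidth_method=config.bandwidth_method,
            epsilon=config.epsilon,
        )
        mat0.meta["config_hash"] = config.config_hash
        io.write_similarity(mat0, out / f"kls_{first.subject_id}.tsv")
        record(out / f"kls_{first.subject_id}.tsv")
        strength_df = pd.DataFrame(
            np.vstack(strength_rows),
            index=[s.subject_id for s in subjects],
            columns=strengths[0].labels,
        )
        strength_df.index.name = "subject_id"
        io.write_matrix(strength_df, out / "nodal_strength.tsv")
        record(out / "nodal_strength.tsv")
        manifest["stages"][stage] = "ok"
    except KlsconnError as exc:
        fail(stage, exc)

    # ---- stage: nodal stats ------------------------------------------
    stage = "nodal_stats"
    try:
        diff = netstats.compare_groups(strengths, design, fdr_alpha=config.fdr_alpha)
        diff.to_frame().to_csv(out / "group_difference.tsv", sep="\t", index=False)
        record(out / "group_difference.tsv")
        io.write_json_summary(
            {
                "config_hash": config.config_hash,
                "fdr_alpha": config.fdr_alpha,
                "covariates": diff.covariates,
                "n_significant": len(diff.significant),
                "significant": diff.significant,
            },
            out / "group_difference_summary.json",
        )
        record(out / "group_difference_summary.json")
        manifest["stages"][stage] = "ok"
    except KlsconnError as exc:
        fail(stage, exc)

    # ---- stage: PLS ---------------------------------------------------
    stage = "pls"
    try:
        gspec = _gene_spec(config, n_regions=len(diff.labels))
        gene_matrix, _ = simulate.generate_gene_matrix(gspec, diff.t_value)
        gene_matrix.index = pd.Index(diff.labels, name="region")
        io.write_gene_matrix(gene_matrix, out / "gene_matrix.tsv")
        io.write_sidecar(out / "gene_matrix.tsv", gspec, seed=gspec.seed)
        record(out / "gene_matrix.tsv")

        y = pd.Series(diff.t_value, index=diff.labels)
        res = transcriptomics.fit_pls(gene_matrix, y)
        res.component_p = transcriptomics.permutation_test_component(
            gene_matrix, y, n_perm=config.n_perm_pls, seed=config.stage_seed("pls_perm")
        )
        res.gene_z = transcriptomics.bootstrap_gene_z(
            gene_matrix, y, n_boot=config.n_boot, seed=config.stage_seed("pls_boot")
        )
        res.n_perm = config.n_perm_pls
        res.n_boot = config.n_boot
        sets = transcriptomics.select_gene_sets(
            res.gene_z, res.gene_labels, z_threshold=config.z_threshold
        )
        per_gene = pd.DataFrame(
            {
                "gene": res.gene_labels,
                "weight": res.gene_weights,
                "z": res.gene_z,
            }
        )
        rs, ps = [], []
        for gene in res.gene_labels:
            r, p = transcriptomics.gene_map_correlation(
                gene_matrix[gene].to_numpy(), diff.t_value
            )
            rs.append(r)
            ps.append(p)
        per_gene["r_with_map"] = rs
        per_gene["p_map"] = ps
        per_gene.to_csv(out / "pls_genes.tsv", sep="\t", index=False)
        record(out / "pls_genes.tsv")
        io.write_json_summary(
            {
                "config_hash": config.config_hash,
                "component_r": res.component_r,
                "component_p": res.component_p,
                "n_perm": res.n_perm,
                "n_boot": res.n_boot,
                "n_pls_plus": len(sets.pls_plus),
                "n_pls_minus": len(sets.pls_minus),
                "z_threshold": sets.z_threshold,
            },
            out / "pls_result.json",
        )
        record(out / "pls_result.json")
        (out / "pls_plus.txt").write_text("\n".join(sets.pls_plus) + "\n")
        (out / "pls_minus.txt").write_text("\n".join(sets.pls_minus) + "\n")
        record(out / "pls_plus.txt")
        record(out / "pls_minus.txt")
        manifest["stages"][stage] = "ok"
    except KlsconnError as exc:
        fail(stage, exc)

    # ---- stage: covariance network ------------------------------------
    stage = "covnet"
    try:
        mspec = _mouse_spec(config)
        tables = simulate.generate_mouse_cohort(mspec)
        nets = {}
        for gname, table in tables.items():
            table.to_csv(out / f"suv_{gname}.tsv", sep="\t", float_format=io.FLOAT_FMT)
            io.write_sidecar(out / f"suv_{gname}.tsv", mspec, seed=mspec.seed)
            record(out / f"suv_{gname}.tsv")
            net = covnet.build_covariance_network(
                table,
                n_perm=config.n_perm_edges,
                alphas=config.alphas,
                seed=config.stage_seed(f"covnet_{gname}"),
                group=gname,
            )
            nets[gname] = net
            for name, matrix in [("r", net.r_matrix), ("edge_p", net.edge_p)] + [
                (f"thr{alpha}", net.thresholded[alpha]) for alpha in config.alphas
            ]:
                df = pd.DataFrame(matrix, index=net.labels, columns=net.labels)
                df.index.name = "region"
                io.write_matrix(df, out / f"covnet_{gname}_{name}.tsv")
                record(out / f"covnet_{gname}_{name}.tsv")
            props = covnet.network_properties(net, alpha=config.alphas[0])
            io.write_json_summary(
                {
                    "config_hash": config.config_hash,
                    "group": gname,
                    "alpha": config.alphas[0],
                    "density": props.density,
                    "hubs_strength": props.hubs_strength,
                    "hubs_degree": props.hubs_degree,
                },
                out / f"covnet_{gname}_properties.json",
            )
            record(out / f"covnet_{gname}_properties.json")
        ga, gb = list(nets)
        ks_stat, ks_p = covnet.compare_edge_distributions(nets[ga], nets[gb])
        edge_diff_p = covnet.compare_edges_between_groups(
            tables[ga],
            tables[gb],
            n_perm=config.n_perm_edges,
            seed=config.stage_seed("covnet_diff"),
        )
        edge_diff_p.to_csv(out / "covnet_edge_diff_p.tsv", sep="\t")
        record(out / "covnet_edge_diff_p.tsv")
        io.write_json_summary(
            {
                "config_hash": config.config_hash,
                "ks_statistic": ks_stat,
                "ks_p": ks_p,
                "n_perm": config.n_perm_edges,
            },
            out / "covnet_ks.json",
        )
        record(out / "covnet_ks.json")
        manifest["stages"][stage] = "ok"
    except KlsconnError as exc:
        fail(stage, exc)

    io.write_json_summary(manifest, out / "manifest.json")
    return manifest
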