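"""End-to-end orchestration: preprocess -> covariance -> impute -> test ->
loci -> cluster -> profiles, driven by one configuration document and one
master seed.

Every stage writes its artifact under the run directory before the next
stage starts, records its parameters in ``manifest.json`` together with a
SHA-256 of each artifact, and derives its randomness from the master seed
via ``numpy.random.SeedSequence.spawn``, so a rerun with the same
configuration reproduces the artifacts byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import os

import numpy as np
import pandas as pd
from scipy import stats

from mtgwas import association, imputation, loci, mixture, profiles
from mtgwas.covariance import empirical_sigma_r
from mtgwas.preprocessing import filter_low_n
from mtgwas.simulate import simulate_ld_panel, simulate_panel_with_ld
from mtgwas.sumstats import ConfigurationError, LDPanel, SumstatsPanel


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict, outdir: str) -> dict:
    """Run the full analysis described by ``config``; returns the manifest.

    Configuration keys (all optional unless noted): ``seed``; ``simulate``
    (generate the input panel and LD reference) or ``inputs`` with ``panel``
    and ``ld_dir`` paths; ``covariance`` (``method``, ``trim_p``);
    ``impute`` (``lambda``, ``quality_threshold``); ``tests``
    (``threshold``); ``cluster`` (``k``, or ``k_range`` with ``n_boot``,
    ``subsample``; ``entropy_threshold``; ``min_snps``).
    """
    os.makedirs(outdir, exist_ok=True)
    manifest: dict = {"config": config, "artifacts": {}, "stages": {}}
    master = int(config.get("seed", 0))
    ss = np.random.SeedSequence(master)
    seeds = {name: int(s.generate_state(1)[0] % (2 ** 31 - 1))
             for name, s in zip(
                 ["simulate", "covariance", "impute", "tests", "cluster",
                  "profiles"], ss.spawn(6))}

    def record(name: str, path: str):
        manifest["artifacts"][name] = {"path": os.path.basename(path),
                                       "sha256": _sha256(path)}

    # -- input stage -------------------------------------------------------
    try:
        if "simulate" in config:
            panel, ld = _simulated_inputs(config["simulate"], seeds["simulate"])
        elif "inputs" in config:
            ld = LDPanel.load(config["inputs"]["ld_dir"])
            panel = SumstatsPanel.load(config["inputs"]["panel"])
        else:
            raise ConfigurationError("config needs 'simulate' or 'inputs'")
    except Exception as e:  # noqa: BLE001 - stage-tagged re-raise
        raise StageError("input", e) from e

    # -- preprocess --------------------------------------------------------
    try:
        frac = config.get("preprocess", {}).get("n_filter_fraction", 0.70)
        panel = filter_low_n(panel, fraction=frac)
        path = os.path.join(outdir, "panel.tsv")
        panel.save(path)
        record("panel", path)
        manifest["stages"]["preprocess"] = {"n_filter_fraction": frac}
    except Exception as e:
        raise StageError("preprocess", e) from e

    # -- covariance --------------------------------------------------------
    try:
        cc = config.get("covariance", {})
        cov = empirical_sigma_r(panel, mode=cc.get("method", "trimmed"),
                                trim_p=cc.get("trim_p", 5e-8),
                                min_pairs=cc.get("min_pairs", 100),
                                seed=seeds["covariance"])
        path = os.path.join(outdir, "sigma_r.tsv")
        cov.save(path)
        record("sigma_r", path)
        manifest["stages"]["covariance"] = {"method": cov.method}
    except Exception as e:
        raise StageError("covariance", e) from e

    # -- imputation --------------------------------------------------------
    try:
        ic = config.get("impute", {})
        panel_imp = imputation.impute_panel(
            panel, ld, lam=ic.get("lambda", 0.1),
            quality_threshold=ic.get("quality_threshold", 0.6))
        path = os.path.join(outdir, "panel_imputed.tsv")
        panel_imp.save(path)
        record("panel_imputed", path)
        manifest["stages"]["impute"] = {
            "n_imputed": int(panel_imp.imputed_mask.sum())}
    except Exception as e:
        raise StageError("impute", e) from e

    # -- tests -------------------------------------------------------------
    try:
        tc = config.get("tests", {})
        threshold = tc.get("threshold", 1e-8)
        stat, df, p_omni = association.omnibus_scan(panel_imp.Z, cov)
        p_univ = 2 * stats.norm.sf(np.abs(panel_imp.Z))
        univ_min = np.nanmin(np.where(np.isnan(p_univ), np.inf, p_univ), axis=1)
        w_r = association.make_weights(cov, scheme="pheno_pc1")
        _, p_sumz_r = association.sumz_scan(panel_imp.Z, w_r, cov)
        w_1 = association.make_weights(cov, scheme="unit")
        _, p_sumz_1 = association.sumz_scan(panel_imp.Z, w_1, cov)
        keep = imputation.post_imputation_qc(panel_imp, ld, p_omni,
                                             p_signif=threshold)
        p_omni_qc = np.where(keep, p_omni, 1.0)
        results = panel_imp.snps.copy()
        results["omnibus_stat"] = stat
        results["omnibus_df"] = df
        results["omnibus_p"] = p_omni_qc
        results["sumz_1_p"] = p_sumz_1
        results["sumz_r_p"] = p_sumz_r
        results["univ_min_p"] = univ_min
        path = os.path.join(outdir, "results.tsv")
        results.to_csv(path, sep="\t", index=False, float_format="%.17g",
                       na_rep="NA")
        record("results", path)
        manifest["stages"]["tests"] = {"threshold": threshold,
                                       "qc_removed": int((~keep).sum())}
    except Exception as e:
        raise StageError("tests", e) from e

    # -- loci --------------------------------------------------------------
    try:
        region_index = ld.regions.assign(panel_imp.snps["chrom"].values,
                                         panel_imp.snps["pos"].values)
        minima = loci.region_minp(p_omni_qc, univ_min, region_index)
        minima = loci.classify_novel(minima, threshold, threshold)
        clumps = loci.clump(p_omni_qc, ld, list(panel_imp.snps["snp_id"]),
                            pos=panel_imp.snps["pos"].values, p1=threshold)
        minima["n_lead_snps"] = [
            sum(region_index[c.lead] == r for c in clumps)
            for r in minima["region"]]
        path = os.path.join(outdir, "loci.tsv")
        minima.to_csv(path, sep="\t", index=False, float_format="%.17g")
        record("loci", path)
        manifest["stages"]["loci"] = {
            "n_novel": int((minima["novelty"] == "multitrait_only").sum()),
            "n_leads": len(clumps)}
    except Exception as e:
        raise StageError("loci", e) from e

    # -- clustering --------------------------------------------------------
    try:
        kc = config.get("cluster", {})
        tracks = {"univ_min": univ_min, "omnibus": p_omni_qc,
                  "sumz_r": p_sumz_r}
        reps = loci.select_cluster_snps(panel_imp, tracks, ld,
                                        threshold=threshold)
        min_snps = kc.get("min_snps", 30)
        manifest["stages"]["cluster"] = {"n_selected": int(reps.size)}
        if reps.size >= min_snps:
            Zsel = panel_imp.Z[reps]
            if "k" in kc:
                k = int(kc["k"])
            else:
                lo, hi = kc.get("k_range", [2, 5])
                sel = mixture.select_k(
                    Zsel, k_range=range(lo, hi + 1),
                    n_boot=kc.get("n_boot", 20),
                    subsample=kc.get("subsample", 0.8), seed=seeds["cluster"])
                k = sel.k
            model = mixture.fit_mgmm(Zsel, k, seed=seeds["cluster"])
            kept, labels = mixture.filter_entropy(
                model, kc.get("entropy_threshold", 0.75))
            assign = panel_imp.snps.iloc[reps[kept]].copy()
            assign["cluster"] = labels
            assign["entropy"] = model.entropies_[kept]
            path = os.path.join(outdir, "assignments.tsv")
            assign.to_csv(path, sep="\t", index=False, float_format="%.17g")
            record("assignments", path)
            model_doc = {"k": int(k),
                         "pi": model.weights_.tolist(),
                         "mu": model.means_.tolist(),
                         "sigma": model.covariances_.tolist()}
            path = os.path.join(outdir, "cluster_model.json")
            with open(path, "w") as fh:
                json.dump(model_doc, fh, indent=1)
            record("cluster_model", path)
            manifest["stages"]["cluster"].update({"k": int(k),
                                                  "n_assigned": int(kept.size)})
            # -- profiles --------------------------------------------------
            pc = config.get("profiles", {})
            Zk = panel_imp.Z[reps[kept]]
            Nk = panel_imp.N[reps[kept]]
            shares = profiles.variance_explained_matrix(
                Zk, Nk, labels, traits=panel_imp.traits,
                display_floor=pc.get("display_floor", 0.001))
            path = os.path.join(outdir, "variance_explained.tsv")
            shares.to_csv(path, sep="\t", index=False, float_format="%.17g")
            record("variance_explained", path)
            B = Zk / np.sqrt(np.where(np.isnan(Nk), np.nan, Nk))
            corr = profiles.cluster_correlation_table(
                np.nan_to_num(B, nan=0.0), np.nanmedian(Nk, axis=0), labels,
                traits=panel_imp.traits)
            path = os.path.join(outdir, "cluster_correlations.tsv")
            corr.to_csv(path, sep="\t", index=False, float_format="%.17g")
            record("cluster_correlations", path)
        else:
            manifest["stages"]["cluster"]["skipped"] = (
                f"only {reps.size} independent significant SNPs "
                f"(< {min_snps}); clustering not attempted")
    except Exception as e:
        raise StageError("cluster", e) from e

    path = os.path.join(outdir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


def _simulated_inputs(sim: dict, seed: int) -> tuple[SumstatsPanel, LDPanel]:
    """Build a synthetic panel + LD reference from a 'simulate' config block.

    Causal SNPs are planted in mixture fashion: ``k_clusters`` mean profiles,
    each claiming an equal share of ``n_causal`` SNPs spread over distinct
    regions."""
    rng = np.random.default_rng(seed)
    K = sim.get("K", 5)
    ld = simulate_ld_panel(n_regions=sim.get("n_regions", 40),
                           snps_per_region=sim.get("snps_per_region", 25),
                           ar_rho=sim.get("ar_rho", 0.8), seed=seed)
    n_snps = sum(len(ids) for ids in ld.region_snps)
    from mtgwas.simulate import random_correlation
    rho = random_correlation(K, rng)
    sigma_r = np.eye(K) * 0.5 + rho * 0.5
    np.fill_diagonal(sigma_r, 1.0)
    effects = np.zeros((n_snps, K))
    n_causal = sim.get("n_causal", 0)
    if n_causal:
        kc = sim.get("k_clusters", 3)
        # equal-norm, mutually separated mean profiles so every planted
        # cluster is equally powered and recoverable
        target = sim.get("effect_scale", 4.0) * np.sqrt(K)
        while True:
            mu = rng.normal(0, 1.0, size=(kc, K))
            mu *= target / np.linalg.norm(mu, axis=1, keepdims=True)
            d = np.linalg.norm(mu[:, None] - mu[None, :], axis=2)
            if (d[np.triu_indices(kc, 1)] >= target).all():
                break
        spr = len(ld.region_snps[0])
        regions = rng.choice(ld.n_regions, size=min(n_causal, ld.n_regions),
                             replace=False)
        for i, r in enumerate(regions):
            snp = r * spr + rng.integers(spr)
            effects[snp] = mu[i % kc] + rng.normal(0, 1, size=K)
    panel = simulate_panel_with_ld(ld, sigma_r, effects=effects,
                                   missing_rate=sim.get("missing_rate", 0.1),
                                   seed=seed + 1)
    return panel, ld
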