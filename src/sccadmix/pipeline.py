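"""End-to-end orchestration of the analysis chain.

A run is described by a YAML configuration (see :data:`DEFAULT_OPTIONS` for
the tunable options and their defaults).  In ``simulate`` mode the run
starts from the synthetic-cohort generator; in ``files`` mode genotypes
(VCF or dosage matrix), a phenotype table, a SNP panel and a pigment-model
coefficient file are supplied.  Stages:

    simulate -> pca -> pigment -> grs -> models (1-4, site strata, negative
    control) -> assoc (per-SNP + conditional) -> lanc (HMM + admixture map)
    -> finemap (credible sets) -> contour -> report

Every output table is tab-separated and carries header lines naming the
seed, package version and configuration hash; the run log records stage
timings.  All stages join on ``individual_id`` — misalignment is an error,
never a silent reindex.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from . import ancestry, io, localanc, riskmodels, summary
from .data import GenotypeData, SNPPanel, check_aligned
from .errors import ConfigError
from .finemap import credible_set
from .pigment import (
    PigmentModel,
    filter_polymorphic,
    predict_skin_probabilities,
)
from .simulate import AncestralPanel, default_study, simulate_study

log = logging.getLogger("sccadmix")

DEFAULT_OPTIONS = {
    "maf_min": 0.01,  # polymorphism filter for pigment/risk/PCA variants
    "k": 15.0,  # contour smoothing value
    "grid_size": 60,
    "grs_weighted": True,
    "prior_w": 0.04,  # fine-mapping prior effect variance (log-odds^2)
    "n_perm": 2000,  # admixture-map permutations
    "alpha": 0.05,
    "n_pcs": None,  # None -> 6 (admixed) or 10 (cline)
    "generations": 10,  # admixture age for the local-ancestry HMM
}

STAGES = (
    "simulate",
    "pca",
    "pigment",
    "grs",
    "models",
    "assoc",
    "lanc",
    "finemap",
    "contour",
    "report",
)


@dataclass
class RunConfig:
    """Validated run configuration."""

    mode: str
    group: str
    seed: int
    outdir: Path
    n_individuals: int = 2000
    options: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    loci: list[str] | None = None
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        mode = cfg.get("mode", "simulate")
        if mode not in ("simulate", "files"):
            raise ConfigError(f"unknown mode {mode!r}")
        group = cfg.get("group", "admixed")
        if group not in riskmodels.GROUP_N_PCS:
            raise ConfigError(f"unknown group {group!r}")
        options = {**DEFAULT_OPTIONS, **cfg.get("options", {})}
        inputs = cfg.get("inputs", {})
        if mode == "files":
            for key in ("genotypes", "phenotypes", "snp_panel", "pigment_model"):
                if key not in inputs:
                    raise ConfigError(f"files mode requires inputs.{key}")
                if not Path(inputs[key]).exists():
                    raise ConfigError(f"input file {inputs[key]} does not exist")
        return cls(
            mode=mode,
            group=group,
            seed=int(cfg.get("seed", 0)),
            outdir=Path(cfg.get("outdir", "sccadmix_out")),
            n_individuals=int(cfg.get("n_individuals", 2000)),
            options=options,
            inputs=inputs,
            loci=cfg.get("loci"),
            raw=cfg,
        )

    @property
    def n_pcs(self) -> int:
        return int(self.options["n_pcs"] or riskmodels.GROUP_N_PCS[self.group])

    def meta(self) -> dict:
        # hash the analytic settings only, so runs written to different
        # directories still compare bit-identically
        analytic = {k: v for k, v in self.raw.items() if k != "outdir"}
        return {"seed": self.seed, "config_hash": io.config_hash(analytic)}


def write_pigment_model(model: PigmentModel, path) -> None:
    rows = [
        {
            "variant_id": "_intercept",
            "effect_allele": "-",
            **{f"coef_cat{i + 2}": model.intercepts[i] for i in range(4)},
        }
    ]
    for j, (vid, ea) in enumerate(zip(model.variant_ids, model.effect_alleles)):
        rows.append(
            {
                "variant_id": vid,
                "effect_allele": ea,
                **{f"coef_cat{i + 2}": model.coefficients[i, j] for i in range(4)},
            }
        )
    io.write_table(pd.DataFrame(rows), path)


def read_pigment_model(path) -> PigmentModel:
    df = io.read_table(path)
    inter = df[df["variant_id"] == "_intercept"]
    if inter.empty:
        raise ConfigError("pigment model file lacks the _intercept row")
    coef_cols = [f"coef_cat{i + 2}" for i in range(4)]
    body = df[df["variant_id"] != "_intercept"].reset_index(drop=True)
    return PigmentModel(
        variant_ids=body["variant_id"].tolist(),
        effect_alleles=body["effect_allele"].tolist(),
        intercepts=inter[coef_cols].to_numpy(dtype=float)[0],
        coefficients=body[coef_cols].to_numpy(dtype=float).T,
    )


def estimate_global_proportions(
    genotypes: GenotypeData, panel: AncestralPanel
) -> np.ndarray:
    """Supervised admixture-proportion estimate per individual.

    Solves, per individual, the non-negative least-squares problem
    ``dosage/2 ≈ Σ_k q_k p_k`` over the panel frequencies and renormalises
    to the simplex — a fast moment estimator adequate for seeding the HMM's
    stationary distribution.
    """
    p = panel.allele_freqs  # (m, K)
    d = np.nan_to_num(genotypes.dosages, nan=np.nanmean(genotypes.dosages)) / 2.0
    out = np.empty((genotypes.n_samples, panel.n_pops))
    for i in range(genotypes.n_samples):
        q, _ = nnls(p, d[i])
        s = q.sum()
        out[i] = q / s if s > 0 else np.full(panel.n_pops, 1.0 / panel.n_pops)
    return out


class PipelineRunner:
    """Executes stages in order, caching intermediates in memory and
    persisting every table to the output directory."""

    def __init__(self, config: RunConfig):
        self.cfg = config
        self.cfg.outdir.mkdir(parents=True, exist_ok=True)
        self._cache: dict[str, object] = {}
        self._timings: list[tuple[str, float]] = []

    # -- inputs ------------------------------------------------------------
    def _load_inputs(self) -> None:
        c = self.cfg
        if c.mode == "simulate":
            design = default_study(c.group, c.n_individuals, c.seed)
            study = simulate_study(design)
            self._cache.update(
                genotypes=study.genotypes,
                phenotypes=study.phenotypes,
                snp_panel=design.snp_panel,
                pigment_model=design.pigment_model,
                ancestral_panel=design.panel,
                truth=study.truth,
            )
        else:
            fmt = c.inputs.get("format", "vcf")
            genotypes = io.read_genotypes(c.inputs["genotypes"], fmt)
            phenotypes = io.read_table(c.inputs["phenotypes"])
            phenotypes["individual_id"] = phenotypes["individual_id"].astype(str)
            check_aligned(genotypes.samples, phenotypes)
            snp_panel = SNPPanel(table=io.read_table(c.inputs["snp_panel"]))
            pig_model = read_pigment_model(c.inputs["pigment_model"])
            freq_cols = [f"freq_{p}" for p in snp_panel.pop_labels]
            anc_panel = None
            if freq_cols and set(snp_panel.table["variant_id"]) >= set(
                genotypes.variant_ids
            ):
                sub = snp_panel.table.set_index("variant_id").loc[
                    genotypes.variant_ids
                ]
                gpos = genotypes.variants.get(
                    "gpos", pd.Series(genotypes.variants["pos"] / 1e8)
                )
                anc_panel = AncestralPanel(
                    pop_labels=snp_panel.pop_labels,
                    variant_ids=genotypes.variant_ids,
                    allele_freqs=np.clip(
                        sub[freq_cols].to_numpy(dtype=float), 0.005, 0.995
                    ),
                    chrom=genotypes.variants["chrom"].to_numpy(),
                    pos_bp=genotypes.variants["pos"].to_numpy(),
                    gpos=np.asarray(gpos, dtype=float),
                )
            self._cache.update(
                genotypes=genotypes,
                phenotypes=phenotypes,
                snp_panel=snp_panel,
                pigment_model=pig_model,
                ancestral_panel=anc_panel,
                truth=None,
            )

    def _get(self, key: str):
        if key not in self._cache:
            self._load_inputs()
        return self._cache[key]

    # -- stages ------------------------------------------------------------
    def stage_simulate(self) -> None:
        c = self.cfg
        genotypes = self._get("genotypes")
        io.write_vcf(genotypes, c.outdir / "genotypes.vcf")
        io.write_table(self._get("phenotypes"), c.outdir / "phenotypes.tsv", c.meta())
        io.write_table(self._get("snp_panel").table, c.outdir / "snp_panel.tsv", c.meta())
        write_pigment_model(self._get("pigment_model"), c.outdir / "pigment_model.tsv")
        truth = self._cache.get("truth")
        if truth is not None:
            ga = pd.DataFrame(truth.global_ancestry, columns=list(truth.pop_labels))
            ga.insert(0, "individual_id", genotypes.samples)
            io.write_table(ga, c.outdir / "truth_global_ancestry.tsv", c.meta())
            lf = pd.DataFrame(
                truth.local_fraction(truth.pop_labels[0]),
                columns=genotypes.variant_ids,
            )
            lf.insert(0, "individual_id", genotypes.samples)
            io.write_table(lf, c.outdir / "truth_local_eur_fraction.tsv", c.meta())

    def stage_pca(self):
        if "pcs" not in self._cache:
            pcs = ancestry.compute_pcs(
                self._get("genotypes"),
                n_components=self.cfg.n_pcs,
                maf_min=self.cfg.options["maf_min"],
            )
            self._cache["pcs"] = pcs
            io.write_table(pcs.frame(), self.cfg.outdir / "pcs.tsv", self.cfg.meta())
        return self._cache["pcs"]

    def stage_pigment(self):
        if "pigment_probs" not in self._cache:
            genotypes = self._get("genotypes")
            model: PigmentModel = self._get("pigment_model")
            kept = filter_polymorphic(
                list(model.variant_ids), genotypes, self.cfg.options["maf_min"]
            )
            probs = predict_skin_probabilities(genotypes, model.subset(kept))
            self._cache["pigment_probs"] = probs
            self._cache["pigment_kept"] = kept
            out = pd.concat([probs.probs5, probs.probs3.add_prefix("c3_")], axis=1)
            out.insert(0, "individual_id", probs.samples)
            io.write_table(out, self.cfg.outdir / "pigment_probs.tsv", self.cfg.meta())
        return self._cache["pigment_probs"]

    def stage_grs(self):
        if "grs" not in self._cache:
            grs = riskmodels.compute_grs(
                self._get("genotypes"),
                self._get("snp_panel"),
                weighted=self.cfg.options["grs_weighted"],
                maf_min=self.cfg.options["maf_min"],
            )
            self._cache["grs"] = grs
            io.write_table(grs.frame(), self.cfg.outdir / "grs.tsv", self.cfg.meta())
        return self._cache["grs"]

    def stage_models(self):
        phen = self._get("phenotypes")
        pcs, probs, grs = self.stage_pca(), self.stage_pigment(), self.stage_grs()
        fits = riskmodels.fit_model_sequence(
            phen, pcs, probs, grs, group=self.cfg.group
        )
        self._cache["model_fits"] = fits
        rows = []
        for name, fit in fits.items():
            s = fit.summary()
            s.insert(0, "model", name)
            s.insert(1, "outcome", "cscc")
            rows.append(s)
        # negative control: ancestry model for the non-cutaneous outcome
        if "ncscc" in phen.columns:
            nc = riskmodels.fit_model_sequence(
                phen, pcs, probs, grs, group=self.cfg.group, outcome="ncscc"
            )["model1"]
            s = nc.summary()
            s.insert(0, "model", "negative_control_model1")
            s.insert(1, "outcome", "ncscc")
            rows.append(s)
        # tumour-site strata: Models 1-2 per site class against all controls
        if "site_class" in phen.columns:
            for stratum in ("sun_exposed", "sun_protected"):
                mask = riskmodels.site_stratum_mask(phen, stratum)
                if phen.loc[mask, "cscc"].sum() < 10:
                    continue
                sub = riskmodels.fit_model_sequence(
                    phen, pcs, probs, grs, group=self.cfg.group, mask=mask
                )
                for mname in ("model1", "model2"):
                    s = sub[mname].summary()
                    s.insert(0, "model", f"{stratum}_{mname}")
                    s.insert(1, "outcome", "cscc")
                    rows.append(s)
        io.write_table(
            pd.concat(rows, ignore_index=True),
            self.cfg.outdir / "models.tsv",
            self.cfg.meta(),
        )
        lrt_rows = []
        for a, b in (("model1", "model2"), ("model2", "model3"), ("model3", "model4")):
            cmp_ = riskmodels.likelihood_ratio_test(fits[a], fits[b])
            lrt_rows.append(
                {
                    "comparison": f"{a}_vs_{b}",
                    "lr_statistic": cmp_.lr_statistic,
                    "df": cmp_.df,
                    "p": cmp_.p_value,
                }
            )
        io.write_table(
            pd.DataFrame(lrt_rows), self.cfg.outdir / "lrt.tsv", self.cfg.meta()
        )
        n_pcs = self.cfg.n_pcs
        baseline = pd.DataFrame(
            {"age": phen["age"].astype(float), "sex": phen["sex"].astype(float)}
        )
        blocks = {
            "ancestry_pcs": pd.DataFrame(
                {f"PC{i + 1}": pcs.scores[:, i] for i in range(n_pcs)}
            ),
            "pigmentation": probs.probs3[["intermediate", "dark"]].reset_index(
                drop=True
            ),
            "grs": pd.DataFrame({"grs": grs.values}),
            "sun_exposure_ak": pd.DataFrame({"ak": phen["ak"].astype(float)}),
        }
        var = riskmodels.variance_explained(
            phen["cscc"].to_numpy(dtype=float), baseline, blocks
        )
        self._cache["variance"] = var
        io.write_table(var.table, self.cfg.outdir / "variance_explained.tsv", self.cfg.meta())
        return fits

    def stage_assoc(self):
        genotypes = self._get("genotypes")
        panel: SNPPanel = self._get("snp_panel")
        phen = self._get("phenotypes")
        pcs = self.stage_pca()
        y = phen["cscc"].to_numpy(dtype=float)
        cov = pd.DataFrame(
            {"age": phen["age"].astype(float), "sex": phen["sex"].astype(float)}
        )
        for i in range(min(self.cfg.n_pcs, pcs.scores.shape[1])):
            cov[f"PC{i + 1}"] = pcs.scores[:, i]
        pig_ids = filter_polymorphic(
            panel.pigment_variant_ids, genotypes, self.cfg.options["maf_min"]
        )
        assoc = riskmodels.per_snp_association(
            genotypes, y, cov, pig_ids, alpha_family=self.cfg.options["alpha"]
        )
        self._cache["assoc_pigment"] = assoc
        meta = {
            **self.cfg.meta(),
            "bonferroni_threshold": assoc.attrs["bonferroni_threshold"],
        }
        io.write_table(assoc, self.cfg.outdir / "assoc_pigment.tsv", meta)
        risk_ids = filter_polymorphic(
            panel.risk_variant_ids, genotypes, self.cfg.options["maf_min"]
        )
        cond = riskmodels.conditional_association(
            genotypes, y, cov, risk_ids, pig_ids, alpha_family=self.cfg.options["alpha"]
        )
        self._cache["assoc_conditional"] = cond
        io.write_table(cond, self.cfg.outdir / "assoc_conditional.tsv", self.cfg.meta())
        return assoc

    def _candidate_loci(self) -> list[str]:
        if self.cfg.loci:
            return list(self.cfg.loci)
        genotypes = self._get("genotypes")
        panel: SNPPanel = self._get("snp_panel")
        return filter_polymorphic(
            panel.risk_variant_ids, genotypes, self.cfg.options["maf_min"]
        )

    def stage_lanc(self):
        genotypes = self._get("genotypes")
        anc_panel = self._get("ancestral_panel")
        phen = self._get("phenotypes")
        if anc_panel is None:
            raise ConfigError(
                "local ancestry requires per-population panel frequencies"
            )
        if genotypes.haplotypes is None:
            raise ConfigError("local ancestry requires phased haplotypes")
        truth = self._cache.get("truth")
        props = (
            truth.global_ancestry
            if truth is not None
            else estimate_global_proportions(genotypes, anc_panel)
        )
        local = localanc.infer_local_ancestry(
            genotypes,
            anc_panel,
            g=int(self.cfg.options["generations"]),
            global_props=props,
        )
        self._cache["local"] = local
        loci = self._candidate_loci()
        result = localanc.admixture_map_test(
            local,
            phen["cscc"].to_numpy(dtype=int),
            loci,
            n_perm=int(self.cfg.options["n_perm"]),
            seed=self.cfg.seed,
            alpha=self.cfg.options["alpha"],
        )
        self._cache["admixture_map"] = result
        meta = {
            **self.cfg.meta(),
            "bonferroni_threshold": result.bonferroni_threshold,
            "n_perm": result.n_perm,
        }
        io.write_table(result.table, self.cfg.outdir / "admixture_map.tsv", meta)
        return result

    def stage_finemap(self):
        genotypes = self._get("genotypes")
        phen = self._get("phenotypes")
        pcs = self.stage_pca()
        cov = pd.DataFrame(
            {"age": phen["age"].astype(float), "sex": phen["sex"].astype(float)}
        )
        for i in range(min(self.cfg.n_pcs, pcs.scores.shape[1])):
            cov[f"PC{i + 1}"] = pcs.scores[:, i]
        y = phen["cscc"].to_numpy(dtype=float)
        loci = self._candidate_loci()
        var = genotypes.variants.set_index("variant_id")
        rows = []
        for locus in loci:
            chrom = var.loc[locus, "chrom"]
            pos = var.loc[locus, "pos"]
            window_ids = var[
                (var["chrom"] == chrom)
                & ((var["pos"] - pos).abs() <= 1_000_000)
            ].index.tolist()
            window_ids = filter_polymorphic(
                window_ids, genotypes, self.cfg.options["maf_min"]
            )
            assoc = riskmodels.per_snp_association(genotypes, y, cov, window_ids)
            assoc = assoc.merge(
                var.reset_index()[["variant_id", "pos"]], on="variant_id"
            ).dropna(subset=["beta", "se"])
            cs = credible_set(
                assoc,
                level=0.95,
                prior_w=self.cfg.options["prior_w"],
                locus=locus,
            )
            out = cs.table.copy()
            out.insert(0, "locus", locus)
            rows.append(out)
        table = pd.concat(rows, ignore_index=True)
        self._cache["finemap"] = table
        io.write_table(table, self.cfg.outdir / "credible_sets.tsv", self.cfg.meta())
        return table

    def stage_contour(self):
        phen = self._get("phenotypes")
        pcs = self.stage_pca()
        grid = ancestry.prevalence_contour(
            pcs,
            phen["cscc"].to_numpy(dtype=float),
            k=float(self.cfg.options["k"]),
            grid_size=int(self.cfg.options["grid_size"]),
        )
        self._cache["contour"] = grid
        io.write_table(grid.frame(), self.cfg.outdir / "contour.tsv", self.cfg.meta())
        return grid

    def stage_report(self):
        phen = self._get("phenotypes")
        table = summary.cohort_table(phen)
        lines = io.header_lines(self.cfg.meta())
        lines.append("")
        lines.append("Cohort summary")
        lines.append(table.to_text())
        fits = self._cache.get("model_fits")
        if fits:
            lines.append("")
            lines.append("Ancestry attenuation (PC1 beta by model)")
            for name, fit in fits.items():
                if fit.converged:
                    lines.append(
                        f"  {name}: beta={fit.coef('PC1'):.3f} "
                        f"se={fit.se('PC1'):.3f} p={fit.pvalue('PC1'):.3g}"
                    )
        amap = self._cache.get("admixture_map")
        if amap is not None:
            n_sig = int(amap.table["significant"].sum())
            lines.append("")
            lines.append(
                f"Admixture map: {n_sig} of {len(amap.table)} loci significant at "
                f"{amap.bonferroni_threshold:.4g}"
            )
        (self.cfg.outdir / "report.txt").write_text("\n".join(lines) + "\n")
        return table

    # -- driver ------------------------------------------------------------
    def run(self, stages: tuple[str, ...] = STAGES) -> None:
        for stage in stages:
            start = time.perf_counter()
            log.info("stage %s: start", stage)
            try:
                getattr(self, f"stage_{stage}")()
            except Exception:
                log.error("stage %s failed; partial outputs kept in %s", stage, self.cfg.outdir)
                raise
            elapsed = time.perf_counter() - start
            self._timings.append((stage, elapsed))
            log.info("stage %s: done in %.2fs", stage, elapsed)
        logpath = self.cfg.outdir / "run_log.json"
        logpath.write_text(
            json.dumps(
                {
                    "seed": self.cfg.seed,
                    "config_hash": self.cfg.meta()["config_hash"],
                    "timings_s": {s: round(t, 3) for s, t in self._timings},
                },
                indent=2,
            )
        )


def run_pipeline(cfg: dict | RunConfig, stages: tuple[str, ...] = STAGES) -> PipelineRunner:
    """Run the configured stages; returns the runner (with cached results)."""
    config = cfg if isinstance(cfg, RunConfig) else RunConfig.from_dict(cfg)
    runner = PipelineRunner(config)
    runner.run(stages)
    return runner
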