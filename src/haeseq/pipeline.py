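"""End-to-end pipeline: simulate -> classify -> de -> dysreg -> coexpr -> varassoc.

A single YAML/JSON config drives all stages; every study constant (the
CC1..CC4 thresholds, the 3.65e-4 significance level, the 30-read minimum,
the 0.7 correlation threshold and 5-gene minimum, CADD 18 and the 0.05
population-frequency cap) is a named config key.  Each stage writes plain
TSV/JSON under its own subdirectory of the run directory; a run manifest
records the config hash, seed, per-stage output checksums and timestamps.
Stages whose outputs already exist are skipped unless an upstream stage was
re-run, so deleting one stage's outputs regenerates only that stage and its
dependents.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from haeseq import clinical, coexpression, de, dysregulation, io as hio, variants
from haeseq.clinical import SeverityThresholds
from haeseq.normalize import collapse_replicates, run_pca, size_factors, vst_transform
from haeseq.simulate import (
    ClinicalModel,
    DEEffect,
    ModuleSpec,
    SimulationConfig,
    VariantSpec,
    simulate_cohort,
)

log = logging.getLogger("haeseq.pipeline")

EXIT_MISSING_INPUT = 3
EXIT_CONFIG = 4
EXIT_THRESHOLDS = 5

STAGES = ("simulate", "classify", "de", "dysreg", "coexpr", "varassoc")


class PipelineError(Exception):
    exit_code = 1


class MissingInputError(PipelineError):
    exit_code = EXIT_MISSING_INPUT


class ConfigError(PipelineError):
    exit_code = EXIT_CONFIG


class ThresholdError(PipelineError):
    exit_code = EXIT_THRESHOLDS


@dataclass
class PipelineConfig:
    simulation: SimulationConfig
    thresholds: SeverityThresholds = field(default_factory=SeverityThresholds)
    de_alpha: float = de.DEFAULT_ALPHA
    de_min_mean: float = de.DEFAULT_MIN_MEAN
    mad_k: float = 5.0
    r_min: float = coexpression.DEFAULT_R_MIN
    min_module_size: int = coexpression.DEFAULT_MIN_SIZE
    family_alpha: float = 0.05
    association_unit: str = "allele"
    association_criterion: str = "cc4"  # which CC defines the tested subgroups

    def __post_init__(self) -> None:
        t = self.thresholds
        if t.cc1_severe_max >= t.cc1_mild_above + 1:
            raise ThresholdError("CC1 severe bound must lie below the mild bound")
        if t.cc2_severe_min < t.cc2_mild_below:
            raise ThresholdError("CC2 severe bound must be >= the mild bound")
        if t.cc3_severe_above < t.cc3_mild_below:
            raise ThresholdError("CC3 severe bound must be >= the mild bound")
        if not 0 < self.de_alpha < 1 or not 0 < self.family_alpha < 1:
            raise ThresholdError("significance levels must be in (0, 1)")
        if self.association_unit not in ("allele", "genotype"):
            raise ConfigError(f"unknown association unit {self.association_unit!r}")
        if self.association_criterion not in ("cc1", "cc2", "cc3", "cc4"):
            raise ConfigError(f"unknown criterion {self.association_criterion!r}")


def _build_simulation(d: dict) -> SimulationConfig:
    d = dict(d)
    if "clinical" in d:
        d["clinical"] = ClinicalModel(**d["clinical"])
    if "de_effects" in d:
        d["de_effects"] = tuple(DEEffect(**e) for e in d["de_effects"])
    if "module_specs" in d:
        d["module_specs"] = tuple(
            ModuleSpec(
                gene_ids=tuple(m["gene_ids"]),
                side_of_gene=dict(m["side_of_gene"]),
                loading_per_subgroup=dict(m["loading_per_subgroup"]),
            )
            for m in d["module_specs"]
        )
    if "variant_specs" in d:
        d["variant_specs"] = tuple(VariantSpec(**v) for v in d["variant_specs"])
    if "nb_mean_log_range" in d:
        d["nb_mean_log_range"] = tuple(d["nb_mean_log_range"])
    if "cell_types" in d:
        d["cell_types"] = tuple(d["cell_types"])
    return SimulationConfig(**d)


def load_config(path, seed: Optional[int] = None) -> PipelineConfig:
    """Parse a YAML/JSON pipeline config; ``seed`` overrides the file's."""
    p = Path(path)
    if not p.exists():
        raise MissingInputError(f"config file not found: {p}")
    try:
        raw = yaml.safe_load(p.read_text()) or {}
    except yaml.YAMLError as e:
        raise ConfigError(f"config does not parse: {e}") from e
    return config_from_dict(raw, seed=seed)


def config_from_dict(raw: dict, seed: Optional[int] = None) -> PipelineConfig:
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    try:
        sim = _build_simulation(raw.get("simulate", {}))
        if seed is not None:
            sim = dataclasses.replace(sim, seed=int(seed))
        thresholds = SeverityThresholds(**raw.get("thresholds", {}))
        de_block = raw.get("de", {})
        coexpr_block = raw.get("coexpr", {})
        var_block = raw.get("varassoc", {})
        return PipelineConfig(
            simulation=sim,
            thresholds=thresholds,
            de_alpha=float(de_block.get("alpha", de.DEFAULT_ALPHA)),
            de_min_mean=float(de_block.get("min_mean", de.DEFAULT_MIN_MEAN)),
            mad_k=float(de_block.get("mad_k", 5.0)),
            r_min=float(coexpr_block.get("r_min", coexpression.DEFAULT_R_MIN)),
            min_module_size=int(
                coexpr_block.get("min_size", coexpression.DEFAULT_MIN_SIZE)
            ),
            family_alpha=float(var_block.get("family_alpha", 0.05)),
            association_unit=str(var_block.get("unit", "allele")),
            association_criterion=str(var_block.get("criterion", "cc4")),
        )
    except PipelineError:
        raise
    except (TypeError, ValueError, KeyError) as e:
        raise ConfigError(f"invalid config: {e}") from e


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(cfg: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (tuple, set, frozenset)):
            return list(o)
        raise TypeError(type(o))

    blob = json.dumps(dataclasses.asdict(cfg), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: list = field(default_factory=list)
    started: str = ""
    finished: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _groups_by_cc(assignments, criterion: str) -> dict[str, list[str]]:
    sev = [a.patient_id for a in assignments if getattr(a, criterion) == "S"]
    mild = [a.patient_id for a in assignments if getattr(a, criterion) == "M"]
    return {"severe": sev, "mild": mild}


def run_pipeline(
    config: PipelineConfig | str | Path,
    outdir,
    seed: Optional[int] = None,
    force: bool = False,
) -> RunManifest:
    """Execute all stages under ``outdir``; returns the manifest.

    Stage outputs that already exist are reused unless ``force`` or an
    upstream stage was re-run.
    """
    if not isinstance(config, PipelineConfig):
        config = load_config(config, seed=seed)
    elif seed is not None:
        config = dataclasses.replace(
            config, simulation=dataclasses.replace(config.simulation, seed=int(seed))
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=_config_hash(config),
        seed=config.simulation.seed,
        version=_version(),
        started=_now(),
    )

    upstream_ran = force
    state: dict = {"config": config}
    for stage_name, runner, outputs in (
        ("simulate", _stage_simulate, _simulate_outputs),
        ("classify", _stage_classify, _fixed_outputs("classify", ["assignments.tsv", "subgroup_summary.tsv"])),
        ("de", _stage_de, _de_outputs),
        ("dysreg", _stage_dysreg, _dysreg_outputs),
        ("coexpr", _stage_coexpr, _coexpr_outputs),
        ("varassoc", _stage_varassoc, _fixed_outputs("varassoc", ["association.tsv", "deleterious.tsv", "segregation.tsv"])),
    ):
        expected = [outdir / p for p in outputs(config)]
        have_all = all(p.exists() for p in expected)
        t0 = time.time()
        if upstream_ran or not have_all:
            log.info(json.dumps({"stage": stage_name, "event": "run"}))
            try:
                runner(config, outdir, state)
            except PipelineError:
                raise
            except FileNotFoundError as e:
                raise MissingInputError(f"{stage_name}: {e}") from e
            upstream_ran = True
            status = "ran"
        else:
            log.info(json.dumps({"stage": stage_name, "event": "skip"}))
            _load_stage_state(stage_name, config, outdir, state)
            status = "skipped"
        manifest.stages.append(
            {
                "name": stage_name,
                "status": status,
                "seconds": round(time.time() - t0, 3),
                "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in expected},
            }
        )
    manifest.finished = _now()
    (outdir / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest


def _now() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime())


def _version() -> str:
    from haeseq import __version__

    return __version__


def _fixed_outputs(stage, names):
    def fn(config):
        return [f"{stage}/{n}" for n in names]

    return fn


def _simulate_outputs(config: PipelineConfig):
    out = ["simulate/patients.tsv", "simulate/variants.vcf",
           "simulate/variant_annotations.tsv", "simulate/truth.json"]
    for cell in config.simulation.cell_types:
        out += [f"simulate/counts_{cell}.tsv", f"simulate/samples_{cell}.tsv"]
    return out


def _de_outputs(config: PipelineConfig):
    out = ["de/serping1_nmd.json"]
    for cell in config.simulation.cell_types:
        out.append(f"de/pca_{cell}.tsv")
        for contrast in ("CC4-M_vs_control", "CC4-S_vs_control", "CC4-S_vs_CC4-M"):
            out.append(f"de/{cell}_{contrast}.tsv")
    return out


def _dysreg_outputs(config: PipelineConfig):
    out = []
    for cell in config.simulation.cell_types:
        out += [
            f"dysreg/per_individual_{cell}.tsv",
            f"dysreg/per_gene_{cell}.tsv",
            f"dysreg/group_comparisons_{cell}.tsv",
        ]
    return out


def _coexpr_outputs(config: PipelineConfig):
    out = ["coexpr/modules.json", "coexpr/module_summaries.tsv"]
    for cell in config.simulation.cell_types:
        for grp in ("control", "CC4-M", "CC4-S"):
            out.append(f"coexpr/corr_{cell}_{grp}.tsv")
    return out


# --------------------------------------------------------------------- stages


def _stage_simulate(config: PipelineConfig, outdir: Path, state: dict) -> None:
    d = outdir / "simulate"
    d.mkdir(exist_ok=True)
    bundle = simulate_cohort(config.simulation)
    hio.write_patients(bundle.patients, d / "patients.tsv")
    for cell, cm in bundle.counts.items():
        hio.write_counts(cm, d / f"counts_{cell}.tsv", d / f"samples_{cell}.tsv")
    ids = [p.patient_id for p in bundle.patients]
    hio.write_variants_vcf(bundle.variants, d / "variants.vcf", ids)
    hio.write_variant_annotations(bundle.variants, d / "variant_annotations.tsv")
    hio.write_truth(bundle.truth, d / "truth.json")
    state["bundle"] = bundle


def _load_stage_state(stage, config, outdir: Path, state: dict) -> None:
    if stage == "simulate":
        d = outdir / "simulate"
        patients = hio.read_patients(d / "patients.tsv")
        counts = {
            cell: hio.read_counts(d / f"counts_{cell}.tsv", d / f"samples_{cell}.tsv")
            for cell in config.simulation.cell_types
        }
        vrecs = hio.read_variants(d / "variants.vcf", d / "variant_annotations.tsv")
        from haeseq.simulate import CohortBundle

        state["bundle"] = CohortBundle(
            patients=patients,
            counts=counts,
            variants=vrecs,
            truth=json.loads((d / "truth.json").read_text()),
            config=config.simulation,
        )
    elif stage == "classify":
        df = pd.read_csv(outdir / "classify" / "assignments.tsv", sep="\t")
        state["assignments"] = [
            clinical.SeverityAssignment(
                patient_id=str(r["patient_id"]),
                cc1=r["cc1"], cc2=r["cc2"], cc3=r["cc3"], cc4=r["cc4"], cc5=r["cc5"],
                asymptomatic=bool(r["asymptomatic"]),
            )
            for _, r in df.iterrows()
        ]
    # later stages keep no state needed downstream


def _stage_classify(config: PipelineConfig, outdir: Path, state: dict) -> None:
    d = outdir / "classify"
    d.mkdir(exist_ok=True)
    bundle = state["bundle"]
    assignments = clinical.classify_cohort(bundle.patients, config.thresholds)
    clinical.assignments_frame(assignments).to_csv(
        d / "assignments.tsv", sep="\t", index=False
    )
    clinical.summarize_subgroups(assignments, bundle.patients).to_csv(
        d / "subgroup_summary.tsv", sep="\t", index=False
    )
    state["assignments"] = assignments


def _collapsed(config: PipelineConfig, state: dict) -> dict:
    if "collapsed" not in state:
        bundle = state["bundle"]
        # CC4 group labels follow the classification stage, so threshold
        # overrides propagate into the DE contrasts.
        cc4 = {a.patient_id: a.cc4 for a in state["assignments"]}
        collapsed = {}
        for cell, cm in bundle.counts.items():
            c = collapse_replicates(cm)
            grp = [
                "control" if c.samples.loc[s, "group"] == "control"
                else ("CC4-S" if cc4.get(c.samples.loc[s, "individual_id"]) == "S" else "CC4-M")
                for s in c.sample_ids
            ]
            c.samples["group"] = grp
            collapsed[cell] = c
        state["collapsed"] = collapsed
    return state["collapsed"]


def _stage_de(config: PipelineConfig, outdir: Path, state: dict) -> None:
    d = outdir / "de"
    d.mkdir(exist_ok=True)
    bundle = state["bundle"]
    contrasts = (
        ("CC4-M_vs_control", "control", "CC4-M"),
        ("CC4-S_vs_control", "control", "CC4-S"),
        ("CC4-S_vs_CC4-M", "CC4-M", "CC4-S"),
    )
    nmd_report = {}
    for cell, cm in _collapsed(config, state).items():
        factors = size_factors(cm.counts)
        vst = vst_transform(cm.counts, factors)
        coords, var_pct = run_pca(vst)
        pca_df = coords.copy()
        pca_df["group"] = cm.samples.loc[coords.index, "group"].to_numpy()
        pca_df.to_csv(d / f"pca_{cell}.tsv", sep="\t", index_label="sample")
        group_sizes = cm.samples["group"].value_counts()
        for name, ga, gb in contrasts:
            if group_sizes.get(ga, 0) < 2 or group_sizes.get(gb, 0) < 2:
                log.warning(json.dumps(
                    {"stage": "de", "cell": cell, "contrast": name,
                     "event": "skipped", "reason": "fewer than 2 per group"}
                ))
                res = pd.DataFrame(
                    columns=["base_mean_a", "base_mean_b", "log2_fold_change",
                             "wald_statistic", "p_value", "p_value_pre_removal",
                             "dispersion", "passes_min_mean", "outliers_removed",
                             "significant"],
                    index=pd.Index([], name="gene"),
                )
            else:
                res = de.differential_expression(
                    cm, ga, gb,
                    alpha=config.de_alpha,
                    min_mean=config.de_min_mean,
                    mad_k=config.mad_k,
                )
            res.to_csv(d / f"{cell}_{name}.tsv", sep="\t")
        classes = pd.Series(
            {p.patient_id: p.serping1_class for p in bundle.patients}
        )
        groups = cm.samples["group"].copy()
        groups.index = cm.samples["individual_id"].to_numpy()
        vst_ind = vst.copy()
        vst_ind.columns = cm.samples.loc[vst.columns, "individual_id"].to_numpy()
        try:
            nmd_report[cell] = de.serping1_nmd_contrast(
                vst_ind, groups, classes, gene=config.simulation.serping1_gene
            )
        except KeyError:
            nmd_report[cell] = None
        state.setdefault("vst", {})[cell] = vst
        state.setdefault("factors", {})[cell] = factors
    (d / "serping1_nmd.json").write_text(json.dumps(nmd_report, indent=2) + "\n")


def _ensure_vst(config, state):
    if "vst" not in state:
        state["vst"], state["factors"] = {}, {}
        for cell, cm in _collapsed(config, state).items():
            f = size_factors(cm.counts)
            state["factors"][cell] = f
            state["vst"][cell] = vst_transform(cm.counts, f)


def _stage_dysreg(config: PipelineConfig, outdir: Path, state: dict) -> None:
    d = outdir / "dysreg"
    d.mkdir(exist_ok=True)
    _ensure_vst(config, state)
    for cell, cm in _collapsed(config, state).items():
        vst = state["vst"][cell]
        factors = state["factors"][cell]
        normed = cm.counts / factors
        groups = cm.samples["group"]
        ctrl = list(groups.index[groups == "control"])
        profile = dysregulation.dysregulation_counts(
            vst, ctrl, alpha=config.de_alpha,
            min_mean=config.de_min_mean, normalized_counts=normed,
        )
        per_ind = profile.per_individual.rename("n_dysregulated").to_frame()
        per_ind["group"] = groups.loc[per_ind.index].to_numpy()
        per_ind.to_csv(d / f"per_individual_{cell}.tsv", sep="\t", index_label="sample")
        profile.per_gene.rename("n_individuals").to_frame().to_csv(
            d / f"per_gene_{cell}.tsv", sep="\t", index_label="gene"
        )
        dysregulation.compare_count_distributions(profile, groups).to_csv(
            d / f"group_comparisons_{cell}.tsv", sep="\t", index=False
        )


def _stage_coexpr(config: PipelineConfig, outdir: Path, state: dict) -> None:
    d = outdir / "coexpr"
    d.mkdir(exist_ok=True)
    _ensure_vst(config, state)
    modules_out = []
    summary_frames = []
    for cell, cm in _collapsed(config, state).items():
        vst = state["vst"][cell]
        groups = cm.samples["group"]
        corr_by = {}
        for grp in ("control", "CC4-M", "CC4-S"):
            ids = list(groups.index[groups == grp])
            if len(ids) < 4:
                log.warning(json.dumps(
                    {"stage": "coexpr", "cell": cell, "subgroup": grp,
                     "event": "skipped", "reason": "fewer than 4 individuals"}
                ))
                empty = pd.DataFrame(index=vst.index, columns=vst.index, dtype=float)
                empty.to_csv(d / f"corr_{cell}_{grp}.tsv", sep="\t")
                continue
            corr = coexpression.pairwise_correlations(vst, ids, grp, cell)
            corr.matrix.to_csv(d / f"corr_{cell}_{grp}.tsv", sep="\t")
            corr_by[grp] = corr
        # module specificity needs every subgroup's correlations
        modules = (
            coexpression.detect_modules(
                corr_by, r_min=config.r_min, min_size=config.min_module_size
            )
            if len(corr_by) == 3
            else []
        )
        for m in modules:
            src = corr_by[m.source_subgroup].matrix
            m.side_a, m.side_b, m.frustration = coexpression.partition_signs(
                m.genes, src
            )
            summ = coexpression.module_summaries(m, corr_by)
            summ = summ.reset_index()
            summ.insert(0, "module", m.module_id)
            summ.insert(1, "cell_type", cell)
            summary_frames.append(summ)
            modules_out.append(
                {
                    "module_id": m.module_id,
                    "cell_type": cell,
                    "source_subgroup": m.source_subgroup,
                    "genes": sorted(m.genes),
                    "side_a": sorted(m.side_a),
                    "side_b": sorted(m.side_b),
                    "frustration": m.frustration,
                }
            )
    (d / "modules.json").write_text(json.dumps(modules_out, indent=2) + "\n")
    if summary_frames:
        pd.concat(summary_frames, ignore_index=True).to_csv(
            d / "module_summaries.tsv", sep="\t", index=False
        )
    else:
        pd.DataFrame(
            columns=["module", "cell_type", "subgroup",
                     "median_within_a", "median_within_b", "median_a_b"]
        ).to_csv(d / "module_summaries.tsv", sep="\t", index=False)


def _stage_varassoc(config: PipelineConfig, outdir: Path, state: dict) -> None:
    d = outdir / "varassoc"
    d.mkdir(exist_ok=True)
    bundle = state["bundle"]
    vrecs = bundle.variants
    kept = variants.filter_deleterious(list(vrecs))
    pd.DataFrame(
        [{"variant": v.key, "gene": v.gene, "consequence": v.consequence} for v in kept]
    ).to_csv(d / "deleterious.tsv", sep="\t", index=False)

    cc = config.association_criterion
    subgroups = _groups_by_cc(state["assignments"], cc)
    all_ids = [p.patient_id for p in bundle.patients]
    if vrecs and all(len(v) >= 1 for v in subgroups.values()):
        assoc = variants.associate(
            vrecs, subgroups, all_ids,
            family_alpha=config.family_alpha, unit=config.association_unit,
        )
    else:
        assoc = pd.DataFrame(
            columns=["variant", "gene", "subgroup", "cohort_freq", "observed_alt",
                     "expected_alt", "n_alleles", "chi_square", "p_value",
                     "min_achievable_p", "testable", "adjusted_alpha", "significant"]
        )
    assoc.to_csv(d / "association.tsv", sep="\t", index=False)

    # family segregation: only families with >= 2 severe and >= 2 mild members
    fam_rows = []
    fams: dict[str, dict[str, str]] = {}
    cc_of = {a.patient_id: getattr(a, cc) for a in state["assignments"]}
    for p in bundle.patients:
        if p.family_id and p.patient_id in cc_of and cc_of[p.patient_id] in ("S", "M"):
            fams.setdefault(p.family_id, {})[p.patient_id] = (
                "severe" if cc_of[p.patient_id] == "S" else "mild"
            )
    for fam, labels in sorted(fams.items()):
        n_s = sum(1 for v in labels.values() if v == "severe")
        n_m = sum(1 for v in labels.values() if v == "mild")
        if n_s < 2 or n_m < 2:
            continue
        for v in vrecs:
            genos = {m: v.genotypes.get(m) for m in labels}
            fam_rows.append(
                {
                    "family": fam,
                    "variant": v.key,
                    "call": variants.segregation_check(genos, labels),
                }
            )
    pd.DataFrame(fam_rows, columns=["family", "variant", "call"]).to_csv(
        d / "segregation.tsv", sep="\t", index=False
    )
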