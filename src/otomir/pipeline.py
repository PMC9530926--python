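"""Config-driven orchestration of the full analysis.

One run = one immutable directory.  Stages execute in a fixed order —
simulate -> dpoae -> de -> screen -> associate -> discriminate -> graph ->
report — each reading only files written by earlier stages, writing
tab-separated outputs, and appending an entry (input hashes, outputs) to a
JSON manifest.  All randomness descends from the single seed in the run
configuration, and floats are serialized with a fixed format, so two runs
with the same config produce byte-identical trees.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import association as assoc
from . import autocm as acm
from . import discriminant as disc
from . import dpoae as dp
from . import expression as expr
from . import screening as screen
from . import synthetic as syn

__all__ = ["RunConfig", "PipelineError", "DependencyError", "run_pipeline", "build_report", "STAGES"]

STAGES = ("simulate", "dpoae", "de", "screen", "associate", "discriminate", "graph", "report")

_FMT = dict(sep="\t", float_format="%.10g")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


class DependencyError(PipelineError):
    """A stage's required input from an earlier stage is missing."""


@dataclass
class RunConfig:
    """Everything a run needs: cohort block, stage toggles, thresholds."""

    seed: int = 0
    n_genes: int = 2000
    mean_depth: float = 1e6
    n_extra_de: int = 44  # extra planted DE genes beyond the 12 coupled ones
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides
    stages: dict = field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    de_alpha: float = 0.01
    screen_threshold: float = 0.3
    screen_min_bands: int = 3
    hl_threshold: float = 29.0
    dp_threshold: float = 16.0
    spls_keep: int = 5
    spls_components: int = 2
    corr_display: float = 0.75
    autocm_C: float | None = None
    autocm_tol: float = 1e-6
    autocm_max_epochs: int = 50
    spinnet_damping: float = 0.95
    spinnet_tol: float = 1e-6

    def __post_init__(self) -> None:
        if not 0 <= self.de_alpha <= 1:
            raise ValueError("de_alpha must lie in [0, 1]")
        if not 0 <= self.screen_threshold <= 1:
            raise ValueError("screen_threshold must lie in [0, 1]")
        if not 0 < self.spinnet_damping < 1:
            raise ValueError("spinnet_damping must lie strictly in (0, 1)")
        if self.spls_keep < 1 or self.spls_components < 1:
            raise ValueError("sPLS parameters must be positive")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage toggle(s): {sorted(unknown)}")
        for s in STAGES:
            self.stages.setdefault(s, True)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls(**(yaml.safe_load(text) or {}))

    def cohort_config(self) -> syn.CohortConfig:
        return syn.CohortConfig(seed=self.seed, **self.cohort)


def _hash_files(paths: list[str]) -> str:
    h = hashlib.sha256()
    for p in sorted(paths):
        h.update(os.path.basename(p).encode())
        with open(p, "rb") as fh:
            h.update(fh.read())
    return h.hexdigest()


def _require(run_dir: str, stage: str, *names: str) -> list[str]:
    paths = [os.path.join(run_dir, n) for n in names]
    missing = [n for n, p in zip(names, paths) if not os.path.exists(p)]
    if missing:
        raise DependencyError(
            f"stage {stage!r}: missing input(s) {missing} — was the producing stage enabled?"
        )
    return paths


def _read(run_dir: str, name: str, **kw) -> pd.DataFrame:
    return pd.read_csv(os.path.join(run_dir, name), sep="\t", index_col=0, **kw)


def _exposed_ids(run_dir: str) -> list[str]:
    """The exposed painters: audiological association, discrimination and
    graph analysis all run within this subset (the control group enters the
    differential-expression contrast only)."""
    cohort = _read(run_dir, "cohort.tsv")
    return list(cohort.index[cohort["group"] != "control"])


def _manifest_update(run_dir: str, stage: str, inputs: list[str], outputs: list[str]) -> None:
    path = os.path.join(run_dir, "manifest.json")
    with open(path) as fh:
        manifest = json.load(fh)
    manifest["stages"][stage] = {
        "inputs_hash": _hash_files(inputs) if inputs else "",
        "outputs": sorted(os.path.basename(o) for o in outputs),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(os.path.join(run_dir, "run.log"), "a") as fh:
        fh.write(f"stage={stage} ok outputs={len(outputs)}\n")


def _stage_simulate(cfg: RunConfig, run_dir: str) -> None:
    effects = syn.PlantedEffects.default(n_extra_de=cfg.n_extra_de)
    tables = syn.generate_cohort(
        cfg.cohort_config(), effects, n_genes=cfg.n_genes, mean_depth=cfg.mean_depth
    )
    syn.write_cohort(tables, run_dir)
    outs = [os.path.join(run_dir, n) for n in
            ("cohort.tsv", "hl.tsv", "dpoae.tsv", "counts.tsv", "condition.tsv")]
    _manifest_update(run_dir, "simulate", [], outs)


def _stage_dpoae(cfg: RunConfig, run_dir: str) -> None:
    """Signal-level DPOAE check: re-derive each subject's band levels from
    synthesized two-component spectra planted at the cohort's levels."""
    (dp_path,) = _require(run_dir, "dpoae", "dpoae.tsv")
    dp_table = _read(run_dir, "dpoae.tsv")
    scheme = dp.BandScheme()
    ss = np.random.SeedSequence([cfg.seed, 404])
    rows = {}
    for k, (subj, levels) in enumerate(dp_table.iterrows()):
        zl = float(levels.mean())
        reps = dp.synthesize_spectrum(
            zl_level=zl, refl_level=zl - 6.0, noise_level=zl - 20.0,
            seed=int(ss.spawn(1)[0].generate_state(1)[0] % (2**31)),
        )
        avg, _snr = dp.coherent_average(reps)
        zl_spec = dp.unmix_zero_latency(avg)
        rows[subj] = dp.band_levels(zl_spec, scheme)
    out = pd.DataFrame(rows).T
    out.index.name = "subject"
    out.columns = [f"DP{int(c)}" for c in out.columns]
    out_path = os.path.join(run_dir, "dpoae_signal.tsv")
    out.to_csv(out_path, **_FMT)
    _manifest_update(run_dir, "dpoae", [dp_path], [out_path])


def _stage_de(cfg: RunConfig, run_dir: str) -> None:
    ins = _require(run_dir, "de", "counts.tsv", "condition.tsv")
    tables = syn.read_cohort(run_dir)
    cm: expr.CountMatrix = tables["counts"]
    cm.norm_factors = expr.tmm_factors(cm)
    table = expr.de_table(cm)
    selected = expr.select_de(table, alpha=cfg.de_alpha)
    de_path = os.path.join(run_dir, "de.tsv")
    sel_path = os.path.join(run_dir, "de_selected.tsv")
    norm_path = os.path.join(run_dir, "norm_counts.tsv")
    table.to_csv(de_path, **_FMT)
    selected.to_csv(sel_path, **_FMT)
    cm.normalized().to_csv(norm_path, **_FMT)
    _manifest_update(run_dir, "de", ins, [de_path, sel_path, norm_path])


def _stage_screen(cfg: RunConfig, run_dir: str) -> None:
    ins = _require(run_dir, "screen", "de_selected.tsv", "norm_counts.tsv",
                   "hl.tsv", "dpoae.tsv", "cohort.tsv")
    exposed = _exposed_ids(run_dir)
    selected = _read(run_dir, "de_selected.tsv")
    norm = _read(run_dir, "norm_counts.tsv")
    hl = _read(run_dir, "hl.tsv").loc[exposed]
    dpo = _read(run_dir, "dpoae.tsv").loc[exposed]
    table = screen.screen_table(
        norm.loc[selected.index, exposed], hl, dpo,
        threshold=cfg.screen_threshold, min_bands=cfg.screen_min_bands,
    )
    path = os.path.join(run_dir, "screen.tsv")
    table.to_csv(path, index=False, **_FMT)
    _manifest_update(run_dir, "screen", ins, [path])


def _stage_associate(cfg: RunConfig, run_dir: str) -> None:
    ins = _require(run_dir, "associate", "screen.tsv", "norm_counts.tsv",
                   "hl.tsv", "dpoae.tsv", "cohort.tsv")
    exposed = _exposed_ids(run_dir)
    screen_df = pd.read_csv(os.path.join(run_dir, "screen.tsv"), sep="\t")
    norm = _read(run_dir, "norm_counts.tsv")
    cohort = _read(run_dir, "cohort.tsv").loc[exposed]
    outcomes = {
        "HL": ("AHL", _read(run_dir, "hl.tsv").loc[exposed]),
        "DPOAE": ("DP", _read(run_dir, "dpoae.tsv").loc[exposed]),
    }
    reports: list[assoc.BetaReport] = []
    hits = screen_df[screen_df["selected"]]
    for _, row in hits.iterrows():
        mirna, outcome = row["mirna"], row["outcome"]
        label, table = outcomes[outcome]
        covs = pd.DataFrame({mirna: np.log2(norm.loc[mirna, exposed] + 1.0)})
        covs["hOGG1"] = cohort["hOGG1"]
        covs.index.name = "subject"
        long = assoc.stack_long(table, covs)
        reports += assoc.fit_band_models(long, mirna, outcome_label=label)
        levels = set(long["hOGG1"])
        if outcome == "DPOAE" and len(levels) >= 2:
            ref = "het" if "het" in levels else sorted(levels)[0]
            reports += assoc.fit_genotype_model(
                long, mirna, genotype="hOGG1", reference=ref, outcome_label=label
            )
    path = os.path.join(run_dir, "betas.tsv")
    assoc.beta_frame(reports).to_csv(path, index=False, **_FMT)
    _manifest_update(run_dir, "associate", ins, [path])


def _stage_discriminate(cfg: RunConfig, run_dir: str) -> None:
    ins = _require(run_dir, "discriminate", "de_selected.tsv", "norm_counts.tsv",
                   "hl.tsv", "dpoae.tsv", "cohort.tsv")
    exposed = _exposed_ids(run_dir)
    selected = _read(run_dir, "de_selected.tsv")
    norm = _read(run_dir, "norm_counts.tsv")
    hl = _read(run_dir, "hl.tsv").loc[exposed]
    dpo = _read(run_dir, "dpoae.tsv").loc[exposed]
    cohort = _read(run_dir, "cohort.tsv").loc[exposed]
    X = np.log2(norm.loc[selected.index, exposed] + 1.0).T  # subjects x genes

    outs = []
    frames = []
    for basis in ("HL_mean", "DPOAE_mean", "hOGG1", "XRCC1"):
        assignments = disc.dichotomize(hl=hl, dpoae=dpo, cohort=cohort, basis=basis)
        adf = disc.assignments_frame(assignments)
        frames.append(adf.assign(basis=basis))
        labels = adf["label"]
        if labels.nunique() < 2 or labels.value_counts().min() < 2:
            with open(os.path.join(run_dir, "run.log"), "a") as fh:
                fh.write(f"stage=discriminate basis={basis} skipped (degenerate groups)\n")
            continue
        model = disc.fit_spls_da(
            X, labels, n_components=cfg.spls_components, keep=cfg.spls_keep
        )
        cases, arrows, direction = disc.biplot_tables(model, corr_cutoff=cfg.corr_display)
        for suffix, df in (
            ("scores", model.scores), ("loadings", model.loadings),
            ("cases", cases), ("arrows", arrows),
        ):
            p = os.path.join(run_dir, f"spls_{basis}_{suffix}.tsv")
            df.to_csv(p, **_FMT)
            outs.append(p)
        pd.DataFrame({"direction": direction}).to_csv(
            os.path.join(run_dir, f"spls_{basis}_direction.tsv"), **_FMT
        )
        outs.append(os.path.join(run_dir, f"spls_{basis}_direction.tsv"))
    gpath = os.path.join(run_dir, "groups.tsv")
    pd.concat(frames).to_csv(gpath, **_FMT)
    _manifest_update(run_dir, "discriminate", ins, outs + [gpath])


def _graph_variables(run_dir: str) -> tuple[pd.DataFrame, dict[str, str]]:
    """Mixed variable table for the map: screened miRNAs, HL, DPOAE, genotypes."""
    exposed = _exposed_ids(run_dir)
    screen_df = pd.read_csv(os.path.join(run_dir, "screen.tsv"), sep="\t")
    norm = _read(run_dir, "norm_counts.tsv")
    hl = _read(run_dir, "hl.tsv").loc[exposed]
    dpo = _read(run_dir, "dpoae.tsv").loc[exposed]
    cohort = _read(run_dir, "cohort.tsv").loc[exposed]
    mirnas = sorted(screen_df.loc[screen_df["selected"], "mirna"].unique())
    raw = pd.concat(
        [
            np.log2(norm.loc[mirnas, exposed] + 1.0).T,
            hl,
            dpo,
            cohort[["hOGG1", "XRCC1"]],
        ],
        axis=1,
    )
    prov = {m: "microRNA" for m in mirnas}
    prov.update({c: "HL" for c in hl.columns})
    prov.update({c: "DPOAE" for c in dpo.columns})
    prov.update({"hOGG1": "polymorphism", "XRCC1": "polymorphism"})
    return raw, prov


def _stage_graph(cfg: RunConfig, run_dir: str) -> None:
    ins = _require(run_dir, "graph", "screen.tsv", "norm_counts.tsv",
                   "hl.tsv", "dpoae.tsv", "cohort.tsv")
    raw, prov = _graph_variables(run_dir)
    scaled = acm.scale_with_complements(raw, provenance=prov)
    model = acm.train_autocm(
        scaled, C=cfg.autocm_C, max_epochs=cfg.autocm_max_epochs, tol=cfg.autocm_tol
    )
    dist = acm.weights_to_distances(model)
    graph = acm.minimum_spanning_tree(dist)
    outs = []
    wpath = os.path.join(run_dir, "autocm_weights.tsv")
    dpath = os.path.join(run_dir, "autocm_distances.tsv")
    model.W.to_csv(wpath, **_FMT)
    dist.to_csv(dpath, **_FMT)
    outs += [wpath, dpath]
    ann = {v: {"provenance": scaled.provenance.get(v, "")} for v in graph.mst.nodes}
    outs += list(acm.export_graph(graph.mst, run_dir, name="mst", annotations=ann))

    # one Spin Net query per audiology-screened miRNA, clamped on the side
    # matching its dominant correlation sign (negative sign -> Min_)
    screen_df = pd.read_csv(os.path.join(run_dir, "screen.tsv"), sep="\t")
    hits = screen_df[screen_df["selected"]].drop_duplicates("mirna")
    queries = []
    for _, row in hits.iterrows():
        prefix = "Min_" if row["dominant_sign"] == "negative" else "Max_"
        var = f"{prefix}{row['mirna']}"
        if var in model.variables:
            queries.append(var)
    for var in queries:
        table, cycles = acm.spinnet_query(
            model, [var], damping=cfg.spinnet_damping, tol=cfg.spinnet_tol
        )
        safe = var.replace("/", "_")
        p = os.path.join(run_dir, f"spinnet_{safe}.tsv")
        table.to_csv(p, index=False, **_FMT)
        outs.append(p)
    _manifest_update(run_dir, "graph", ins, outs)


def build_report(run_dir: str) -> list[str]:
    """Assemble the summary tables from a completed run directory.

    Emits: a DE + screening summary (name, regulation, log2fc, p,
    correlation sign, audiological variable), the beta-coefficient table,
    activation tables per Spin Net query when present, and the group
    assignment summary.
    """
    outs: list[str] = []
    _require(run_dir, "report", "de_selected.tsv", "screen.tsv")
    de_sel = _read(run_dir, "de_selected.tsv")
    screen_df = pd.read_csv(os.path.join(run_dir, "screen.tsv"), sep="\t")
    hits = screen_df[screen_df["selected"]]
    rows = []
    for _, row in hits.iterrows():
        if row["mirna"] not in de_sel.index:
            continue
        de_row = de_sel.loc[row["mirna"]]
        rows.append(
            {
                "mirna": row["mirna"],
                "regulation": de_row["regulation"],
                "log2fc": de_row["log2fc"],
                "p": de_row["p"],
                "p_adj": de_row["p_adj"],
                "correlation_sign": row["dominant_sign"],
                "audiological_variable": row["outcome"],
            }
        )
    t1 = os.path.join(run_dir, "report_de_screen.tsv")
    pd.DataFrame(rows).to_csv(t1, index=False, **_FMT)
    outs.append(t1)

    betas = os.path.join(run_dir, "betas.tsv")
    if os.path.exists(betas):
        t2 = os.path.join(run_dir, "report_betas.tsv")
        df = pd.read_csv(betas, sep="\t")
        df["beta_se"] = [
            f"{b:.3f}{s if s != 'n.s.' else ''} ({e:.3f})"
            for b, s, e in zip(df["beta"], df["stars"], df["se"])
        ]
        df.to_csv(t2, index=False, **_FMT)
        outs.append(t2)

    spin = sorted(
        f for f in os.listdir(run_dir) if f.startswith("spinnet_") and f.endswith(".tsv")
    )
    if spin:
        frames = []
        for f in spin:
            df = pd.read_csv(os.path.join(run_dir, f), sep="\t").head(18)
            df.insert(0, "query", f[len("spinnet_"):-len(".tsv")])
            frames.append(df)
        t3 = os.path.join(run_dir, "report_activations.tsv")
        pd.concat(frames).to_csv(t3, index=False, **_FMT)
        outs.append(t3)
    else:
        with open(os.path.join(run_dir, "run.log"), "a") as fh:
            fh.write("stage=report notice=no spinnet outputs; activation section omitted\n")

    groups = os.path.join(run_dir, "groups.tsv")
    if os.path.exists(groups):
        t4 = os.path.join(run_dir, "report_groups.tsv")
        gdf = pd.read_csv(groups, sep="\t")
        summary = gdf.groupby(["basis", "label"]).size().rename("n").reset_index()
        summary.to_csv(t4, index=False, **_FMT)
        outs.append(t4)
    _manifest_update(run_dir, "report", [], outs)
    return outs


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "dpoae": _stage_dpoae,
    "de": _stage_de,
    "screen": _stage_screen,
    "associate": _stage_associate,
    "discriminate": _stage_discriminate,
    "graph": _stage_graph,
}


def run_pipeline(config: RunConfig, run_dir: str | os.PathLike) -> str:
    """Execute every enabled stage in order into ``run_dir``."""
    run_dir = str(run_dir)
    os.makedirs(run_dir, exist_ok=True)
    cfg_yaml = config.to_yaml()
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": yaml.safe_load(cfg_yaml),
        "config_hash": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "stages": {},
    }
    with open(os.path.join(run_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(os.path.join(run_dir, "config.yaml"), "w") as fh:
        fh.write(cfg_yaml)
    with open(os.path.join(run_dir, "run.log"), "w") as fh:
        fh.write(f"run seed={config.seed} version={__version__}\n")

    for stage in STAGES:
        if not config.stages.get(stage, True):
            continue
        try:
            if stage == "report":
                build_report(run_dir)
            else:
                _STAGE_FUNCS[stage](config, run_dir)
        except DependencyError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return run_dir
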