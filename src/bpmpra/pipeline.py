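"""End-to-end run orchestration: simulate -> demux -> usage -> k-mers -> energy.

A :class:`RunConfig` captures every parameter and seed of a run and
round-trips losslessly through YAML.  :func:`run_pipeline` executes all
stages, writes each intermediate artifact as TSV/JSON plus a manifest of
content hashes, and :func:`render_report` renders a deterministic markdown
summary whose numbers are all traceable to artifact files.

Stage seeds are spawned from the single run seed, so a fixed config yields
byte-identical artifacts.  With ``via_reads`` the simulated transcripts are
round-tripped through FASTQ emission and demultiplexing; otherwise the
simulator's truth table feeds the analysis directly (the default for large
desk-scale runs).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import demux, kmers, usage
from .demux import FilterConfig
from .energy import compare_energies, predict_bp
from .simulate import (
    CONDITIONS,
    DEFAULT_SCAFFOLD,
    K700E,
    WT,
    SpliceModelParams,
    emit_reads,
    generate_library,
    simulate_transcripts,
    write_library_tsv,
)

__all__ = ["RunConfig", "run_pipeline", "render_report", "load_artifacts", "demo_config"]

log = logging.getLogger("bpmpra")


@dataclass
class RunConfig:
    """Full parameterisation of a pipeline run (serialises to YAML)."""

    outdir: str = "bpmpra_run"
    seed: int = 1
    # simulation
    n_minigenes: int = 20_000
    depth: int = 50
    lambda_k700e: float = 0.4
    beta_bp: float = 1.0
    beta_ppt: float = 2.0
    sa2_bonus: float = -1.3
    novel_penalty: float = -4.0
    bp_window_lo: int = -50
    bp_window_hi: int = -10
    # read emission / demux
    via_reads: bool = False
    read_len: int = 50
    error_rate: float = 0.0
    max_mismatch: int = 1
    min_flank: int = 15
    # filtering / analysis
    min_reads: int = 5
    region: str = "25A"
    k: int = 6
    pseudocount: float = 0.5
    or_threshold: float = 1.5

    def params(self, lam: float) -> SpliceModelParams:
        return SpliceModelParams(
            beta_bp=self.beta_bp,
            beta_ppt=self.beta_ppt,
            sa2_bonus=self.sa2_bonus,
            novel_penalty=self.novel_penalty,
            lambda_minus1=lam,
            bp_search_window=(self.bp_window_lo, self.bp_window_hi),
            seed=self.seed,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def demo_config(outdir: str = "bpmpra_demo", seed: int = 1) -> RunConfig:
    """The baked-in desk-scale demonstration run (20k minigenes, lambda 0.4)."""
    return RunConfig(outdir=outdir, seed=seed)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    names = ["library", "sim_WT", "sim_K700E", "reads_WT", "reads_K700E"]
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage of the analysis; returns the result bundle.

    Writes: config.yaml, library.tsv, transcripts_{cond}.tsv (filtered),
    demux_report.json (when ``via_reads``), usage.json, partition.json,
    kmer_stats_{region}_{cond}.tsv, delta_log2_{region}.tsv, census.json,
    top_enhancers_{region}.tsv, energy.json, novel_pfm.tsv, report.md and
    manifest.json under ``cfg.outdir``.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)
    manifest: dict = {"seed": cfg.seed, "stage_seeds": seeds, "stages": []}
    t_all = time.time()

    def stage(name: str, fn):
        t0 = time.time()
        try:
            out = fn()
        except Exception as exc:  # pragma: no cover - error path
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest["stages"].append({"stage": name, "seconds": round(time.time() - t0, 3)})
        log.info("stage %s done in %.1fs", name, time.time() - t0)
        return out

    cfg.to_yaml(outdir / "config.yaml")

    library = stage("simulate.library", lambda: generate_library(
        cfg.n_minigenes, DEFAULT_SCAFFOLD, seeds["library"]))
    write_library_tsv(library, outdir / "library.tsv")

    lam = {WT: 1.0, K700E: cfg.lambda_k700e}
    truth: dict[str, pd.DataFrame] = {}
    for cond in CONDITIONS:
        truth[cond] = stage(f"simulate.transcripts.{cond}", lambda c=cond: simulate_transcripts(
            library, c, cfg.params(lam[c]), cfg.depth, seeds[f"sim_{c}"]))

    tables: dict[str, pd.DataFrame] = {}
    demux_reports = {}
    if cfg.via_reads:
        for cond in CONDITIONS:
            r1 = outdir / f"reads_{cond}_R1.fastq"
            r2 = outdir / f"reads_{cond}_R2.fastq"
            sidecar = outdir / f"truth_{cond}.tsv"
            stage(f"emit_reads.{cond}", lambda c=cond, a=r1, b=r2, s=sidecar: emit_reads(
                truth[c], library, a, b, s, cfg.read_len, cfg.error_rate,
                seeds[f"reads_{c}"], cfg.min_flank))
            tables[cond], demux_reports[cond] = stage(
                f"demux.{cond}", lambda c=cond, a=r1, b=r2: demux.build_transcript_table(
                    a, b, library, c, cfg.max_mismatch, cfg.min_flank))
        _write_json(demux_reports, outdir / "demux_report.json")
    else:
        for cond in CONDITIONS:
            truth[cond].to_csv(outdir / f"truth_{cond}.tsv", sep="\t", index=False)
            tables[cond] = demux.truth_to_table(truth[cond])

    fcfg = FilterConfig(min_reads=cfg.min_reads, require_both_conditions=True)
    tables = stage("apply_filters", lambda: demux.apply_filters(tables, fcfg))
    for cond in CONDITIONS:
        tables[cond].to_csv(outdir / f"transcripts_{cond}.tsv", sep="\t", index=False)

    summaries = {cond: usage.usage_fractions(tables[cond]) for cond in CONDITIONS}
    fold = usage.sa1_fold_change(summaries[WT], summaries[K700E])
    # two-sided test of condition effect on SA1 transcript usage
    sa1 = {c: summaries[c]["transcript_fractions"]["SA1"] * summaries[c]["n_reads"]
           for c in CONDITIONS}
    tot = {c: summaries[c]["n_reads"] for c in CONDITIONS}
    contab = [[sa1[WT], tot[WT] - sa1[WT]], [sa1[K700E], tot[K700E] - sa1[K700E]]]
    effect_p = float(sps.chi2_contingency(contab)[1]) if min(tot.values()) > 0 else 1.0
    usage_out = {
        "per_condition": summaries,
        "sa1_fold_change_k700e_vs_wt": fold,
        "condition_effect_pvalue": effect_p,
        "condition_effect_detected": bool(effect_p < 0.01),
    }
    _write_json(usage_out, outdir / "usage.json")

    partition = stage("partition_sa1", lambda: usage.partition_sa1(tables[WT], tables[K700E]))
    _write_json(partition, outdir / "partition.json")

    _, pfm = stage("novel_ss_context", lambda: usage.novel_ss_context(
        pd.concat([tables[WT], tables[K700E]]), library))
    usage.write_pfm(pfm, outdir / "novel_pfm.tsv")
    n_novel = int(pfm.attrs["n_sequences"])

    kstats = {}
    for cond in CONDITIONS:
        kstats[cond] = stage(f"kmer.compute_all.{cond}", lambda c=cond: kmers.compute_all(
            library, tables[c], cfg.region, cfg.pseudocount, cfg.k))
        kstats[cond].to_csv(outdir / f"kmer_stats_{cfg.region}_{cond}.tsv",
                            sep="\t", index=False)
    delta = stage("kmer.delta_log2", lambda: kmers.delta_log2(kstats[WT], kstats[K700E]))
    delta.to_csv(outdir / f"delta_log2_{cfg.region}.tsv", sep="\t", index=False)

    census = kmers.classification_census()
    _write_json(
        {r.motif_class: {"count": int(r.count), "percent": r.percent}
         for r in census.itertuples(index=False)},
        outdir / "census.json")

    ranked, shares = stage("kmer.top_enhancers", lambda: kmers.top_enhancers(
        delta, cfg.or_threshold, by="delta"))
    ranked_or, shares_or = kmers.top_enhancers(delta, cfg.or_threshold, by="OR")
    ranked.to_csv(outdir / f"top_enhancers_{cfg.region}.tsv", sep="\t", index=False)

    energy_out = stage("energy.compare", lambda: _energy_comparison(
        library, tables, cfg))
    _write_json(energy_out, outdir / "energy.json")

    results = {
        "config": dataclasses.asdict(cfg),
        "usage": usage_out,
        "partition": partition,
        "n_novel_sites": n_novel,
        "census": {r.motif_class: int(r.count) for r in census.itertuples(index=False)},
        "enhancers": {
            "n_delta_ranked": int(len(ranked)),
            "class_shares_delta": shares,
            "n_or_ranked": int(len(ranked_or)),
            "class_shares_or": shares_or,
        },
        "energy": energy_out,
        "demux_reports": demux_reports,
        "tables": tables,
        "delta": delta,
        "ranked": ranked,
        "library": library,
    }

    report_md = render_report(results)
    (outdir / "report.md").write_text(report_md)

    manifest["wall_seconds"] = round(time.time() - t_all, 3)
    manifest["artifacts"] = {
        p.name: _sha256(p) for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    _write_json(manifest, outdir / "manifest.json")
    results["manifest"] = manifest
    return results


def _energy_comparison(library, tables, cfg: RunConfig) -> dict:
    """Predicted SA1 branch-point energies: shared vs K700E-only minigenes.

    A single (WT, lambda=1) energy model scores both sets, as a descriptive
    comparison of which branch points each genotype ends up using.
    """
    part = usage.partition_sa1(tables[WT], tables[K700E])
    wt_ids = set(tables[WT].loc[tables[WT]["acceptor_class"] == "SA1", "minigene_id"])
    k_ids = set(tables[K700E].loc[tables[K700E]["acceptor_class"] == "SA1", "minigene_id"])
    shared, k_only = wt_ids & k_ids, k_ids - wt_ids
    by_id = {m.id: m for m in library}
    dparams = cfg.params(1.0).duplex
    window = (cfg.bp_window_lo, cfg.bp_window_hi)

    def energies(ids):
        out = []
        for mg_id in ids:
            mg = by_id[mg_id]
            cand = predict_bp(mg.full_seq[: mg.sa1_pos], window, dparams, "WT")
            if cand is not None:
                out.append(cand.delta_g)
        return out

    e_shared, e_konly = energies(shared), energies(k_only)
    if not e_shared or not e_konly:
        return {"skipped": "empty SA1 set", "partition": part}
    cmp = compare_energies(e_shared, e_konly, labels=("shared", "k700e_only"))
    cmp["partition"] = part
    return cmp


def load_artifacts(outdir: str | Path) -> dict:
    """Rebuild a renderable result bundle from a run directory's artifacts.

    Missing artifacts are listed under ``"missing"`` and their report
    sections degrade gracefully (partial render).
    """
    outdir = Path(outdir)
    missing: list[str] = []

    def _json(name, default):
        p = outdir / name
        if not p.exists():
            missing.append(name)
            return default
        return json.loads(p.read_text())

    cfg = RunConfig.from_yaml(outdir / "config.yaml") if (outdir / "config.yaml").exists() \
        else RunConfig(outdir=str(outdir))
    usage_out = _json("usage.json", {
        "per_condition": {c: {"transcript_fractions": {"SA1": float("nan"),
                                                       "SA2": float("nan"),
                                                       "NOVEL": float("nan")},
                              "minigene_sa1_ratio": None, "n_reads": 0}
                          for c in CONDITIONS},
        "sa1_fold_change_k700e_vs_wt": None,
        "condition_effect_pvalue": None, "condition_effect_detected": True})
    partition = _json("partition.json", {"n_sa1_minigenes": 0,
                                         "counts": {}, "percent": {
                                             "shared": 0, "k700e_only": 0, "wt_only": 0}})
    census_raw = _json("census.json", {})
    census = {cls: v.get("count", 0) for cls, v in census_raw.items()}
    energy_out = _json("energy.json", {"skipped": "artifact missing"})
    delta_path = outdir / f"delta_log2_{cfg.region}.tsv"
    ranked_path = outdir / f"top_enhancers_{cfg.region}.tsv"
    if ranked_path.exists():
        ranked = pd.read_csv(ranked_path, sep="\t")
        if len(ranked):
            vc = ranked["motif_class"].value_counts()
            shares = {c: 100.0 * int(vc.get(c, 0)) / len(ranked) for c in vc.index}
        else:
            shares = {}
    else:
        missing.append(ranked_path.name)
        ranked, shares = pd.DataFrame(
            columns=["kmer", "or_wt", "or_k700e", "delta_log2", "motif_class"]), {}
    if not delta_path.exists():
        missing.append(delta_path.name)
    pfm_path = outdir / "novel_pfm.tsv"
    if pfm_path.exists():
        pfm = pd.read_csv(pfm_path, sep="\t", index_col=0)
        n_novel = int(pfm.iloc[:, 0].sum())
    else:
        missing.append(pfm_path.name)
        n_novel = 0
    return {
        "config": dataclasses.asdict(cfg),
        "usage": usage_out,
        "partition": partition,
        "census": census,
        "n_novel_sites": n_novel,
        "enhancers": {"n_delta_ranked": int(len(ranked)), "class_shares_delta": shares,
                      "n_or_ranked": None, "class_shares_or": None},
        "energy": energy_out,
        "ranked": ranked,
        "missing": missing,
    }


def _fmt(x, nd=4):
    if x is None:
        return "NA"
    if isinstance(x, float):
        return f"{x:.{nd}g}"
    return str(x)


def render_report(results: dict) -> str:
    """Render the human-readable markdown summary of a result bundle."""
    cfg = results["config"]
    u = results["usage"]
    part = results["partition"]
    lines = [
        "# Minigene 3'SS competition report",
        "",
    ]
    if results.get("missing"):
        lines += ["**Partial render; missing artifacts:** "
                  + ", ".join(results["missing"]), ""]
    lines += [
        f"Run seed {cfg['seed']}; {cfg['n_minigenes']} minigenes, mean depth "
        f"{cfg['depth']}, lambda_K700E = {cfg['lambda_k700e']}, region {cfg['region']}.",
        "",
        "## Acceptor usage",
        "",
        "| condition | SA1 | SA2 | NOVEL | minigene SA1 ratio |",
        "|---|---|---|---|---|",
    ]
    for cond in CONDITIONS:
        s = u["per_condition"][cond]
        f = s["transcript_fractions"]
        lines.append(
            f"| {cond} | {_fmt(f['SA1'])} | {_fmt(f['SA2'])} | {_fmt(f['NOVEL'])} "
            f"| {_fmt(s['minigene_sa1_ratio'])} |"
        )
    lines += [
        "",
        f"SA1 fold change (K700E/WT): {_fmt(u['sa1_fold_change_k700e_vs_wt'])}",
        "",
    ]
    if not u["condition_effect_detected"]:
        lines.append("**No condition effect detected** (SA1 usage p = "
                     f"{_fmt(u['condition_effect_pvalue'])}).")
    else:
        lines.append(f"Condition effect on SA1 usage: p = {_fmt(u['condition_effect_pvalue'])}.")
    lines += [
        "",
        "## SA1 minigene partition",
        "",
        f"{part['n_sa1_minigenes']} SA1-utilizing minigenes: "
        f"{_fmt(part['percent']['shared'], 3)}% shared, "
        f"{_fmt(part['percent']['k700e_only'], 3)}% K700E-only, "
        f"{_fmt(part['percent']['wt_only'], 3)}% WT-only.",
        "",
        "## Branch-point motif census (all 4096 6-mers)",
        "",
        "| class | count |",
        "|---|---|",
    ]
    census = results["census"]
    for cls, count in census.items():
        lines.append(f"| {cls} | {count} |")
    total = sum(census.values())
    lines += [f"| total | {total} |", ""]

    enh = results["enhancers"]
    lines += [
        "## Mutant-preferred splicing enhancers "
        f"(OR > {cfg['or_threshold']} in K700E, delta_log2 > 0)",
        "",
        f"{enh['n_delta_ranked']} 6-mers survive; class shares (%): "
        + ", ".join(f"{k} {_fmt(v, 3)}" for k, v in enh["class_shares_delta"].items()),
        "",
        "Top 10 by delta_log2:",
        "",
        "| kmer | OR WT | OR K700E | delta_log2 | class |",
        "|---|---|---|---|---|",
    ]
    ranked = results["ranked"]
    for row in ranked.head(10).itertuples(index=False):
        lines.append(
            f"| {row.kmer} | {_fmt(row.or_wt)} | {_fmt(row.or_k700e)} "
            f"| {_fmt(row.delta_log2)} | {row.motif_class} |"
        )
    if len(ranked) == 0:
        lines.append("| (none) | | | | |")
    lines += ["", "## Novel 3'SS", ""]
    if results["n_novel_sites"] == 0:
        lines.append("No novel acceptors observed.")
    else:
        lines.append(
            f"{results['n_novel_sites']} distinct novel acceptor sites; upstream "
            "position frequency matrix in novel_pfm.tsv.")
    lines += ["", "## U2-BP duplex energetics (predicted SA1 branch points)", ""]
    e = results["energy"]
    if "skipped" in e:
        lines.append(f"Energy comparison skipped: {e['skipped']}.")
    else:
        lines.append(
            f"Mean dG shared = {_fmt(e['mean_a'])} kcal/mol (n={e['n_a']}), "
            f"K700E-only = {_fmt(e['mean_b'])} kcal/mol (n={e['n_b']}); "
            f"less stable set: {e['less_stable']}; Wilcoxon rank-sum p = {_fmt(e['pvalue'], 3)}.")
    lines.append("")
    return "\n".join(lines)
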