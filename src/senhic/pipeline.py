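"""End-to-end orchestration of the synthetic validation run, plus the
statistical reporting helpers shared by the analysis layers.

``run_pipeline`` executes the analysis stages in dependency order
(matrix ops -> compartments -> domains -> loops -> differential
interactions -> 3D model) on a simulated condition pair, writing every
result table under the output directory together with a manifest.  A
stage failure aborts its dependents but independent stages still run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import traceback
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import compartments as comp
from . import dci as dcimod
from . import domains as dom
from . import loops as lp
from . import matrix as mx
from . import model3d as m3
from . import simulate as sim

log = logging.getLogger("senhic")

STAGES = ("matrix", "compartments", "domains", "loops", "dci", "model3d")


@dataclass
class RunConfig:
    """Configuration of a full synthetic validation run."""

    outdir: str = "senhic_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    # generator
    domain_depth: float = 5_000_000.0
    loop_depth: float = 30_000_000.0
    compartment_depth: float = 2_000_000.0
    compartment_amplitude: float = 0.6
    amplitude_scale_perturbed: float = 0.5
    tad_scale_perturbed: float = 0.5
    n_drop_loops: int = 10
    # analysis
    mask_fraction: float = 0.0   # synthetic maps have no unmappable bins
    insulation_window_bp: int = 500_000
    min_tad_bins: int = 20
    loop_fdr: float = 0.1
    dci_flank_bp: int = 80_000
    dci_min: int = 10
    log_level: str = "INFO"

    def params_hash(self) -> str:
        d = asdict(self)
        d.pop("outdir", None)  # analysis parameters only, not run location
        d.pop("log_level", None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:10]


def _write(df: pd.DataFrame, path: Path, config: RunConfig, module: str) -> Path:
    """Write a result table with a provenance header line."""
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# module={module} params={config.params_hash()} seed={config.seed}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Simulate a condition pair and run every enabled analysis stage.

    Returns the manifest (also written as manifest.json): stage status
    plus the list of output files.
    """
    logging.basicConfig(level=config.log_level, stream=sys.stderr)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "params": config.params_hash(),
                      "stages": {}, "files": []}
    ctx: dict = {}

    def record(stage: str, status: str, err: str | None = None):
        manifest["stages"][stage] = {"status": status}
        if err:
            manifest["stages"][stage]["error"] = err

    deps = {
        "matrix": (),
        "compartments": ("matrix",),
        "domains": ("matrix",),
        "loops": ("matrix", "domains"),
        "dci": ("matrix", "domains"),
        "model3d": ("matrix", "domains"),
    }
    runners = {
        "matrix": _stage_matrix,
        "compartments": _stage_compartments,
        "domains": _stage_domains,
        "loops": _stage_loops,
        "dci": _stage_dci,
        "model3d": _stage_model3d,
    }
    for stage in STAGES:
        if stage not in config.stages:
            record(stage, "skipped")
            continue
        unmet = [d for d in deps[stage]
                 if manifest["stages"].get(d, {}).get("status") != "ok"]
        if unmet:
            record(stage, "aborted", f"unmet dependencies: {unmet}")
            continue
        try:
            files = runners[stage](config, out, ctx)
            manifest["files"].extend(str(f.relative_to(out)) for f in files)
            record(stage, "ok")
            log.info("stage %s ok (%d files)", stage, len(files))
        except Exception as e:  # pragma: no cover - defensive
            record(stage, "failed", f"{e}\n{traceback.format_exc(limit=2)}")
            log.error("stage %s failed: %s", stage, e)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _stage_matrix(config: RunConfig, out: Path, ctx: dict) -> list[Path]:
    files = []
    dcfg = sim.domain_config(seed=config.seed, depth=config.domain_depth,
                             perturbation=sim.Perturbation(
                                 tad_scale=config.tad_scale_perturbed))
    ctx["domain_cfg"] = dcfg
    for cond in ("baseline", "perturbed"):
        cm, gt = sim.simulate_matrix(dcfg, cond)
        bal = mx.ice_balance(cm, mask_fraction=config.mask_fraction)
        ctx[f"raw_{cond}"], ctx[f"bal_{cond}"], ctx[f"truth_{cond}"] = cm, bal, gt
        files.extend(mx.write_hicpro(cm, out / f"matrix_{cond}"))
        dec = mx.contact_decay(cm, fit_range=(200_000, 2_000_000))
        p = out / f"decay_{cond}.tsv"
        _write(dec.table, p, config, "matrix")
        files.append(p)
        ctx[f"decay_{cond}"] = dec
    tracks = sim.simulate_tracks(dcfg)
    ctx["tracks"] = tracks
    tracks.write(out / "tracks")
    files.extend(sorted((out / "tracks").glob("*")))
    return files


def _stage_compartments(config: RunConfig, out: Path, ctx: dict) -> list[Path]:
    files = []
    ccfg = sim.compartment_config(
        seed=config.seed, amplitude=config.compartment_amplitude,
        depth=config.compartment_depth,
        perturbation=sim.Perturbation(amplitude_scale=config.amplitude_scale_perturbed),
    )
    tracks = sim.simulate_tracks(ccfg)
    acc = tracks.accessibility["value"].to_numpy()
    profs = {}
    for cond in ("baseline", "perturbed"):
        cm, _ = sim.simulate_matrix(ccfg, cond)
        bal = mx.ice_balance(cm, mask_fraction=config.mask_fraction)
        prof = comp.call_pc1(bal, acc)
        profs[cond] = prof
        prof.to_bedgraph(out / f"pc1_{cond}.bedgraph")
        files.append(out / f"pc1_{cond}.bedgraph")
        sad = comp.saddle_strength(bal, prof)
        p = _write(pd.DataFrame(sad.matrix), out / f"saddle_{cond}.tsv", config, "compartments")
        files.append(p)
        pen = comp.pentad_strength(bal, prof)
        p = _write(pen.strengths, out / f"pentad_{cond}.tsv", config, "compartments")
        files.append(p)
        ctx[f"saddle_{cond}"], ctx[f"pentad_{cond}"] = sad, pen
    switches = comp.classify_switches(profs["baseline"], profs["perturbed"])
    p = _write(switches, out / "switch_classes.tsv", config, "compartments")
    files.append(p)
    ctx["switches"] = switches
    ctx["comp_profiles"] = profs
    return files


def _stage_domains(config: RunConfig, out: Path, ctx: dict) -> list[Path]:
    files = []
    tadsets = {}
    for cond in ("baseline", "perturbed"):
        bal = ctx[f"bal_{cond}"]
        ins = dom.insulation(bal, config.insulation_window_bp)
        ins.to_bedgraph(out / f"insulation_{cond}.bedgraph")
        files.append(out / f"insulation_{cond}.bedgraph")
        tads = dom.call_tads(ins, config.min_tad_bins)
        stab = dom.tad_stability(bal, tads)
        merged = tads.table.merge(stab, left_index=True, right_on="tad")
        p = _write(merged, out / f"tads_{cond}.tsv", config, "domains")
        files.append(p)
        tadsets[cond] = tads
        ctx[f"tads_{cond}"], ctx[f"stab_{cond}"], ctx[f"ins_{cond}"] = tads, stab, ins
        ata = dom.ata_pileup(bal, tads)
        p = _write(pd.DataFrame(ata.pileup), out / f"ata_{cond}.tsv", config, "domains")
        files.append(p)
    rear = dom.classify_rearrangements(tadsets["baseline"], tadsets["perturbed"])
    p = _write(rear, out / "rearrangements.tsv", config, "domains")
    files.append(p)
    ctx["rearrangements"] = rear
    # differential TADs on the dedicated many-TAD genome (the detector
    # needs a mostly-null per-TAD score cloud)
    dtcfg = sim.difftad_config(seed=config.seed,
                               scale=config.tad_scale_perturbed)
    tset = dom.tadset_from_bounds([(t.start, t.end) for t in dtcfg.tads],
                                  dtcfg.bin_size)
    s1 = dom.tad_stability(sim.simulate_matrix(dtcfg, "baseline")[0], tset)["iTC"]
    s2 = dom.tad_stability(sim.simulate_matrix(dtcfg, "perturbed")[0], tset)["iTC"]
    dt = dom.diff_tads(s1, s2)
    p = _write(dt.table, out / "diff_tads.tsv", config, "domains")
    files.append(p)
    return files


def _stage_loops(config: RunConfig, out: Path, ctx: dict) -> list[Path]:
    files = []
    lcfg = sim.loop_config(seed=config.seed)
    lcfg.perturbation = sim.Perturbation(
        drop_loops=tuple(range(min(config.n_drop_loops, len(lcfg.loops))))
    )
    calls = {}
    mats = {}
    for cond in ("baseline", "perturbed"):
        cm, gt = sim.simulate_matrix(lcfg, cond)
        bal = mx.ice_balance(cm, mask_fraction=config.mask_fraction)
        ls = lp.call_loops(cm, bal, fdr=config.loop_fdr)
        calls[cond], mats[cond] = ls, cm
        ls.to_bedpe(out / f"loops_{cond}.bedpe")
        files.append(out / f"loops_{cond}.bedpe")
        a = lp.apa(bal, ls)
        p = _write(pd.DataFrame(a.pileup), out / f"apa_{cond}.tsv", config, "loops")
        files.append(p)
        ctx[f"apa_{cond}"] = a
    d = lp.diff_loops(calls["baseline"], calls["perturbed"],
                      mats["baseline"], mats["perturbed"])
    p = _write(d.table, out / "diff_loops.tsv", config, "loops")
    files.append(p)
    ctx["diff_loops"] = d
    ctx["loop_calls"] = calls
    return files


def _stage_dci(config: RunConfig, out: Path, ctx: dict) -> list[Path]:
    files = []
    dcfg = sim.dci_config(seed=config.seed)
    tabs = []
    for cond in ("baseline", "perturbed"):
        for rep in range(2):
            cm, _ = sim.simulate_matrix(dcfg, cond, rep)
            tabs.append(dcimod.pixel_table(cm, max_span_bp=2_000_000))
    norm = dcimod.joint_normalize(tabs)
    res = dcimod.dci_test(norm[:2], norm[2:], dcfg.bin_size)
    res.write(out / "dci.tsv")
    files.append(out / "dci.tsv")
    tads = ctx["tads_baseline"]
    tracks = ctx["tracks"]
    cov = pd.DataFrame({
        "accessibility": tracks.accessibility["value"].to_numpy(),
        "ctcf": tracks.ctcf["value"].to_numpy(),
    })
    rear = ctx.get("rearrangements")
    summary, corr = dcimod.tad_dci_summary(
        res, tads, covariates=cov, rearrangement=rear,
        flank_bp=config.dci_flank_bp, min_dci=config.dci_min,
    )
    p = _write(summary, out / "tad_dci_summary.tsv", config, "dci")
    files.append(p)
    if len(corr):
        p = _write(corr, out / "dci_correlations.tsv", config, "dci")
        files.append(p)
    ctx["dci"], ctx["dci_summary"] = res, summary
    return files


def _stage_model3d(config: RunConfig, out: Path, ctx: dict) -> list[Path]:
    files = []
    tads = ctx["tads_baseline"]
    # focus on the largest TAD; focus bin at its center
    spans = [(e - s, k) for k, (s, e) in enumerate(tads.bounds())]
    _, k = max(spans)
    s, e = tads.bounds()[k]
    profs = {}
    for cond in ("baseline", "perturbed"):
        bal = ctx[f"bal_{cond}"]
        _, oe = mx.observed_expected(bal)
        sub = oe[s:e, s:e]
        st = m3.embed_structure(sub, seed=config.seed, restarts=3)
        st.to_tsv(out / f"structure_{cond}.tsv")
        st.to_pdb(out / f"structure_{cond}.pdb")
        files.extend([out / f"structure_{cond}.tsv", out / f"structure_{cond}.pdb"])
        profs[cond] = m3.distance_profile(st, (e - s) // 2)
    rep = compare_profiles_report(profs["baseline"], profs["perturbed"])
    p = _write(pd.DataFrame([rep]), out / "focus_distance.tsv", config, "model3d")
    files.append(p)
    ctx["focus_profiles"] = profs
    return files


def compare_profiles_report(p1, p2) -> dict:
    rep = m3.compare_profiles(p1, p2)
    rep["stars"] = stars(rep["p"])
    return rep


# ---------------------------------------------------------------------------
# Statistical reporting
# ---------------------------------------------------------------------------

def stars(p: float) -> str:
    """Figure-legend significance convention."""
    if not np.isfinite(p) or p > 0.05:
        return "ns"
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    return "*"


@dataclass
class StatReport:
    test: str
    statistic: float
    p: float
    n: int
    stars: str


def stat_compare(values_1, values_2, paired: bool = False, test: str = "wilcoxon") -> StatReport:
    """Run one of the reporting tests and map the p-value to stars.

    ``test``: 'wilcoxon' (paired flag decides signed-rank vs rank-sum),
    't' (paired or Welch), 'spearman', 'fisher' (two 2-vectors forming a
    2x2 table).
    """
    x = np.asarray(values_1, dtype=float)
    y = np.asarray(values_2, dtype=float)
    if test != "fisher" and (x.size < 3 or y.size < 3):
        raise ValueError("need at least 3 observations per group")
    if paired and x.size != y.size:
        raise ValueError("paired comparison requires equal lengths")
    if test == "wilcoxon":
        if paired:
            if np.allclose(x, y):
                res_stat, p = 0.0, 1.0
            else:
                r = stats.wilcoxon(x, y)
                res_stat, p = float(r.statistic), float(r.pvalue)
        else:
            r = stats.mannwhitneyu(x, y, alternative="two-sided")
            res_stat, p = float(r.statistic), float(r.pvalue)
        name = "paired Wilcoxon" if paired else "unpaired Wilcoxon"
    elif test == "t":
        r = stats.ttest_rel(x, y) if paired else stats.ttest_ind(x, y, equal_var=False)
        res_stat, p = float(r.statistic), float(r.pvalue)
        name = "paired t" if paired else "Welch t"
    elif test == "spearman":
        r = stats.spearmanr(x, y)
        res_stat, p = float(r.statistic), float(r.pvalue)
        name = "Spearman"
    elif test == "fisher":
        tab = np.array([x, y], dtype=float)
        res_stat, p = stats.fisher_exact(tab)
        name = "Fisher"
    else:
        raise ValueError(f"unknown test '{test}'")
    if not np.isfinite(p):
        p = 1.0
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return StatReport(test=name, statistic=res_stat, p=p, n=int(x.size), stars=stars(p))
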