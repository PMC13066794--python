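"""End-to-end orchestration: simulate/ingest -> preprocess -> geometry ->
stats -> decoding -> sequential, from one YAML-able config, with CSV tables,
JSON sidecars, basic figure analogues and a Markdown report."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import decoding, geometry, preprocess, sequential, stats, synthetic
from .session import RecordingSession, WindowSpec, read_session

log = logging.getLogger("afterimage")

KNOWN_ANALYSES = ("geometry", "decoding", "sequential")

DEFAULT_WINDOWS = {
    "spikes": {"on": (0.0, 4.0), "off": (0.0, 4.0), "iti": (0.0, 20.0)},
    "traces": {"on": (0.0, 5.0), "off": (0.0, 5.0), "iti": (0.0, 50.0)},
}


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def _validate_config(config: dict) -> None:
    for a in config.get("analyses", []):
        if a not in KNOWN_ANALYSES:
            raise ValueError(
                f"unknown analysis {a!r}; known: {', '.join(KNOWN_ANALYSES)}")


def _get_session(config: dict) -> RecordingSession:
    if "input" in config and config["input"]:
        return read_session(config["input"],
                            config.get("input_format", "text"))
    sim = dict(config.get("simulate", {}))
    sim.setdefault("seed", config.get("seed", 0))
    if "odors" in sim:
        sim["odors"] = tuple(sim["odors"])
    cfg = synthetic.SyntheticConfig(**sim)
    session, _ = synthetic.generate_session(cfg)
    return session


def _windows(session: RecordingSession, config: dict) -> dict[str, WindowSpec]:
    defaults = DEFAULT_WINDOWS[session.modality]
    w = dict(defaults, **config.get("windows", {}))
    on_s = tuple(w["on"])
    return {
        "on": WindowSpec("ON", on_s[0], on_s[1], "odor_onset"),
        "off": WindowSpec("OFF", w["off"][0], w["off"][1], "odor_offset"),
        "iti": WindowSpec("ITI", w["iti"][0], w["iti"][1], "odor_offset"),
    }


def _bin_kw(session: RecordingSession, config: dict) -> dict:
    return {
        "bin_width_s": config.get("bin_width_s", 0.05),
        "frames_per_bin": config.get("frames_per_bin", 4),
    }


def _geometry_stage(session, windows, config, outdir, seed) -> dict[str, Path]:
    kw = _bin_kw(session, config)
    tables = {}
    rows = []
    angle_rows = []
    for odor in session.odors:
        on = preprocess.response_matrix(session, odor, windows["on"], **kw)
        off = preprocess.response_matrix(session, odor, windows["off"], **kw)
        on_on, off_off, on_off = geometry.angle_distributions(on, off)
        for aset in (on_on, off_off, on_off):
            angle_rows.extend(
                {"odor": odor, "group": aset.group, "angle_deg": a}
                for a in aset.angles_deg)
        rows.append({
            "odor": odor,
            "median_on_on_deg": on_on.median(),
            "median_off_off_deg": off_off.median(),
            "median_on_off_deg": on_off.median(),
        })
    med = pd.DataFrame(rows)
    null = geometry.random_vector_null(session.n_units(), rng=seed)
    test = stats.wilcoxon_vs_90(med["median_on_off_deg"])
    summary = pd.DataFrame([{
        "method": test.method, "statistic": test.statistic,
        "p": test.p_value, "n": test.n[0], "sidedness": test.sidedness,
        "random_null_median_deg": null.median(),
    }])
    tables["angles"] = _write_table(pd.DataFrame(angle_rows), outdir, "angles")
    tables["angle_medians"] = _write_table(med, outdir, "angle_medians")
    tables["angle_tests"] = _write_table(summary, outdir, "angle_tests")

    vectors = {}
    for odor in session.odors:
        on = preprocess.response_matrix(session, odor, windows["on"], **kw)
        off = preprocess.response_matrix(session, odor, windows["off"], **kw)
        vectors[(odor, "ON")] = preprocess.time_average(on)
        vectors[(odor, "OFF")] = preprocess.time_average(off)
    C = geometry.period_correlation(vectors)
    labels = [f"{o}:{p}" for o, p in C.row_index]
    corr = pd.DataFrame(C.values, index=labels, columns=labels)
    tables["period_correlation"] = _write_table(
        corr.reset_index().rename(columns={"index": "condition"}),
        outdir, "period_correlation")

    Z, leaf = geometry.cluster_angular({f"{o}:{p}": v
                                        for (o, p), v in vectors.items()})
    (outdir / "cluster.nwk").write_text(geometry.linkage_to_newick(Z, leaf) + "\n")
    return tables


def _decoding_stage(session, windows, config, outdir, seed) -> dict[str, Path]:
    kw = _bin_kw(session, config)
    k = config.get("k", 10)
    n_perm = config.get("n_perm", 1000)
    bin_w = config.get("decoding_bin_width_s", 0.2)
    tables = {}
    for name, window in (("on", windows["on"]), ("iti", windows["iti"])):
        res = decoding.timecourse_decoding(
            session, window, bin_width_s=bin_w,
            frames_per_bin=kw["frames_per_bin"], k=k)
        res = decoding.decoding_significance(res, n_perm=n_perm, seed=seed)
        rows = []
        for b, t in enumerate(res.bin_centers_s):
            for c, odor in enumerate(res.odors):
                rows.append({
                    "window": name, "odor": odor, "time_bin_s": t,
                    "accuracy": res.accuracy_by_odor[c, b],
                    "overall_accuracy": res.overall_accuracy[b],
                    "null_mean": res.null_mean[b], "p": res.p_values[b],
                    "significant": bool(res.significant_bins[b]),
                })
        tables[f"decoding_{name}"] = _write_table(
            pd.DataFrame(rows), outdir, f"decoding_{name}")
        sidecar = dict(res.params, seed=seed, chance=res.chance,
                       n_vectors=res.n_vectors)
        (outdir / f"decoding_{name}.json").write_text(
            json.dumps(sidecar, indent=2, default=str))
    return tables


def _sequential_stage(session, windows, config, outdir, seed) -> dict[str, Path]:
    ref = config.get("reference_odor")
    if ref is None:
        seq_trials = [t for t in session.trials if len(t.odor_sequence) == 2]
        if not seq_trials:
            raise ValueError("sequential analysis needs sequential trials")
        ref = seq_trials[0].odor_sequence[1][0]
    comp = sequential.sequential_contrast(session, ref,
                                          bin_width_s=_bin_kw(session, config)["bin_width_s"],
                                          frames_per_bin=_bin_kw(session, config)["frames_per_bin"])
    rows = [{"reference": ref, "context": c, "corr_solitary": s,
             "corr_sequential": q, "delta": q - s}
            for c, s, q in comp.pairs]
    df = pd.DataFrame(rows)
    if comp.test is not None:
        df["paired_t_p"] = comp.test.p_value
        df["paired_t_stat"] = comp.test.statistic
    return {"sequential": _write_table(df, outdir, "sequential")}


def _write_table(df: pd.DataFrame, outdir: Path, name: str) -> Path:
    path = outdir / f"{name}.csv"
    df.to_csv(path, index=False, float_format="%.6g")
    return path


def run_pipeline(config: dict, output_dir: str | Path) -> Path:
    """Run the configured stages on one session; returns the output dir.

    Tables are CSV with a config-hash/seed sidecar; a report.md summarizes
    each analysis; determinism: config + seed fully determine all tables.
    """
    _validate_config(config)
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    chash = _config_hash(config)
    logging.basicConfig(level=config.get("log_level", "INFO"))
    log.info("run %s (seed=%d)", chash, seed)

    session = _get_session(config)
    windows = _windows(session, config)
    if session.modality == "traces" and session.meta.get("dff") != "true":
        session = preprocess.dff_session(session)

    tables: dict[str, Path] = {}
    analyses = config.get("analyses", ["geometry", "decoding"])
    for stage in analyses:
        log.info("stage: %s", stage)
        try:
            fn = {"geometry": _geometry_stage, "decoding": _decoding_stage,
                  "sequential": _sequential_stage}[stage]
            tables.update(fn(session, windows, config, outdir, seed))
        except Exception:
            log.exception("stage %s failed; partial outputs kept in %s",
                          stage, outdir)
            raise

    (outdir / "run.json").write_text(json.dumps(
        {"config_hash": chash, "seed": seed, "config": config}, indent=2,
        default=str))
    _report(tables, outdir, chash, seed)
    figure_analogues(tables, outdir)
    return outdir


def _report(tables: dict[str, Path], outdir: Path, chash: str,
            seed: int) -> None:
    lines = [f"# afterimage run report", "",
             f"config hash: `{chash}`  seed: {seed}", ""]
    for name, path in sorted(tables.items()):
        df = pd.read_csv(path)
        lines.append(f"## {name}")
        lines.append("")
        lines.append(f"{len(df)} rows -> `{path.name}`")
        head = df.head(8)
        lines.append("")
        lines.append(head.to_string(index=False))
        lines.append("")
    (outdir / "report.md").write_text("\n".join(lines))


def figure_analogues(tables: dict[str, Path], outdir: Path) -> list[Path]:
    """Basic static plots: angle histograms with a 90-degree reference,
    correlation heatmaps, decoding accuracy traces with null band and
    significance ticks.  Missing tables are skipped with a warning."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    made = []
    if "angles" in tables:
        df = pd.read_csv(tables["angles"])
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for grp, sub in df.groupby("group"):
            ax.hist(sub["angle_deg"], bins=60, alpha=0.5, density=True,
                    label=grp)
            ax.axvline(sub["angle_deg"].median(), ls="--", lw=0.8)
        ax.axvline(90, color="k", lw=1)
        ax.set_xlabel("angular separation (deg)")
        ax.set_ylabel("density")
        ax.legend(fontsize=7)
        fig.tight_layout()
        p = outdir / "angles_hist.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        made.append(p)
    if "period_correlation" in tables:
        df = pd.read_csv(tables["period_correlation"]).set_index("condition")
        fig, ax = plt.subplots(figsize=(4.5, 4))
        im = ax.imshow(df.values, vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_xticks(range(len(df)), df.columns, rotation=90, fontsize=6)
        ax.set_yticks(range(len(df)), df.index, fontsize=6)
        fig.colorbar(im, ax=ax, label="Pearson r")
        fig.tight_layout()
        p = outdir / "period_correlation.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        made.append(p)
    for name in ("decoding_on", "decoding_iti"):
        if name not in tables:
            continue
        df = pd.read_csv(tables[name]).drop_duplicates("time_bin_s")
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.plot(df["time_bin_s"], df["overall_accuracy"], "k-", label="observed")
        ax.plot(df["time_bin_s"], df["null_mean"], color="gray", label="null mean")
        sig = df[df["significant"]]
        if len(sig):
            ax.plot(sig["time_bin_s"], np.full(len(sig), 1.02), "s",
                    ms=2, color="C1")
        ax.set_ylim(0, 1.08)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("accuracy")
        ax.legend(fontsize=7)
        fig.tight_layout()
        p = outdir / f"{name}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        made.append(p)
    missing = set(tables) - {"angles", "angle_medians", "angle_tests",
                             "period_correlation", "decoding_on",
                             "decoding_iti", "sequential"}
    for name in missing:
        log.warning("no figure analogue for table %s; skipped", name)
    return made
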