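"""Reproducible simulate -> decode -> generalize -> stats -> source runs.

A run is described by a :class:`RunConfig` (YAML or JSON on disk), executed
by :func:`run_pipeline` into an output directory of TSV/JSON artifacts plus
a manifest, and rendered by :func:`report`. All randomness flows from the
master seed through a deterministic seed tree (per stage, per subject), so
a second run with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .decoding import TemporalDecoder, decode_eyetrack
from .epochs import TimeWindow
from .simulate import SimulationConfig, simulate_group
from .source import LCMVBeamformer, atlas_average
from .stats import (
    cluster_permutation_vs_chance,
    correlation_test,
    median_split_compare,
    specificity_index,
)

__all__ = ["RunConfig", "run_pipeline", "report"]

logger = logging.getLogger("tgdecode")

KNOWN_ANALYSES = (
    "diagonal",
    "tg_within",
    "tg_cross",
    "specificity",
    "eyetrack",
    "vividness_split",
    "source",
)

# analyses that consume the outputs of an earlier stage
_DEPENDS = {
    "specificity": ("diagonal", "tg_within"),
    "vividness_split": ("diagonal",),
    "eyetrack": ("diagonal",),
}


def derive_seed(master: int, *keys: int) -> int:
    """Deterministic child seed below 2**31 from a master seed and key path."""
    ss = np.random.SeedSequence([int(master) & 0x7FFFFFFF, *[int(k) for k in keys]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Full description of a pipeline run."""

    simulation: SimulationConfig
    k_folds: int = 5
    window_ms: float = 30.0
    n_perm: int = 1000
    cluster_alpha: float = 0.05
    analyses: list[str] = field(
        default_factory=lambda: ["diagonal", "tg_within", "tg_cross", "specificity"]
    )
    out_dir: str = "run"
    seed: int = 0
    source_n_perm: int = 200
    source_cov_window: TimeWindow | None = None
    source_power_window: TimeWindow | None = None

    def __post_init__(self) -> None:
        for a in self.analyses:
            if a not in KNOWN_ANALYSES:
                raise ValueError(f"unknown analysis {a!r}; known: {KNOWN_ANALYSES}")
        if "source" in self.analyses and not self.simulation.source_space:
            raise ValueError("source analysis requires simulation.source_space = true")
        ew = self.simulation.epoch_window
        if self.source_cov_window is None:
            self.source_cov_window = TimeWindow(0.05, ew.end_s)
        if self.source_power_window is None:
            self.source_power_window = TimeWindow(0.1, min(0.7, ew.end_s))

    # -- config (de)serialization -------------------------------------
    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = dict(d.pop("simulation", {}))
        for key in ("epoch_window", "imagery_window"):
            if key in sim and sim[key] is not None:
                sim[key] = TimeWindow(*sim[key])
        if "pattern_times" in sim and sim["pattern_times"] is not None:
            sim["pattern_times"] = [TimeWindow(*w) for w in sim["pattern_times"]]
        for key in ("source_cov_window", "source_power_window"):
            if key in d and d[key] is not None:
                d[key] = TimeWindow(*d[key])
        return cls(simulation=SimulationConfig(**sim), **d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        return cls.from_dict(yaml.safe_load(text))

    def to_dict(self) -> dict:
        def unwin(w):
            return None if w is None else [w.start_s, w.end_s]

        sim = asdict(self.simulation)
        sim["epoch_window"] = unwin(self.simulation.epoch_window)
        sim["imagery_window"] = unwin(self.simulation.imagery_window)
        sim["pattern_times"] = [unwin(w) for w in self.simulation.pattern_times]
        return {
            "simulation": sim,
            "k_folds": self.k_folds,
            "window_ms": self.window_ms,
            "n_perm": self.n_perm,
            "cluster_alpha": self.cluster_alpha,
            "analyses": list(self.analyses),
            "out_dir": self.out_dir,
            "seed": self.seed,
            "source_n_perm": self.source_n_perm,
            "source_cov_window": unwin(self.source_cov_window),
            "source_power_window": unwin(self.source_power_window),
        }

    def canonical_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    def hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def _matrix_frame(times_r, times_c, values, row_name) -> pd.DataFrame:
    return pd.DataFrame(
        values,
        index=pd.Index(times_r, name=row_name),
        columns=[f"{t:.6g}" for t in times_c],
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured analyses; return (and write) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "version": __import__("tgdecode").__version__,
        "stages": {},
    }

    def stage(name):
        manifest["stages"][name] = {"status": "pending", "outputs": []}
        return manifest["stages"][name]

    def record(st, *paths):
        st["outputs"].extend(str(Path(p).relative_to(out)) for p in paths)

    # ---- simulate ----------------------------------------------------
    st = stage("simulate")
    sim_cfg = SimulationConfig(**{**asdict_shallow(config.simulation),
                                  "seed": derive_seed(config.seed, 0)})
    group = simulate_group(sim_cfg)
    st["status"] = "ok"
    st["n_subjects"] = len(group)
    logger.info("simulated %d subjects (scenario=%s)", len(group), sim_cfg.scenario)

    state: dict = {"group": group}
    failed: set[str] = set()

    for analysis in config.analyses:
        deps = _DEPENDS.get(analysis, ())
        if any(d in failed or (d in config.analyses and
                               manifest["stages"].get(d, {}).get("status") == "failed")
               for d in deps):
            stage(analysis)["status"] = "skipped (failed dependency)"
            continue
        st = stage(analysis)
        try:
            _run_analysis(analysis, config, state, out, st, record)
            st["status"] = "ok"
        except Exception as exc:  # noqa: BLE001 - recorded in manifest
            logger.exception("stage %s failed", analysis)
            st["status"] = "failed"
            st["error"] = f"{type(exc).__name__}: {exc}"
            failed.add(analysis)

    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest


def asdict_shallow(sim: SimulationConfig) -> dict:
    d = {f: getattr(sim, f) for f in sim.__dataclass_fields__}
    return d


def _run_analysis(name, config: RunConfig, state, out: Path, st, record) -> None:
    group = state["group"]
    n_perm, alpha = config.n_perm, config.cluster_alpha
    kw = dict(k_folds=config.k_folds, window_ms=config.window_ms)

    if name == "diagonal":
        for ci, cond in enumerate(("perception", "imagery")):
            courses = []
            for i, subj in enumerate(group):
                tc = TemporalDecoder(getattr(subj, cond), **kw).fit_diagonal(
                    seed=derive_seed(config.seed, 1, i)
                )
                path = out / f"diag_{cond}_{tc.subject_id}.tsv"
                tc.to_tsv(path)
                record(st, path)
                courses.append(tc)
            maps = np.stack([c.accuracy for c in courses])
            res = cluster_permutation_vs_chance(
                maps, 0.5, n_perm=n_perm, cluster_alpha=alpha,
                seed=derive_seed(config.seed, 2, ci),
            )
            res.to_json(out / f"diag_{cond}_clusters.json")
            grand = pd.DataFrame({
                "time_s": courses[0].times,
                "accuracy": maps.mean(axis=0),
                "sem": maps.std(axis=0, ddof=1) / np.sqrt(maps.shape[0]),
                "significant": res.mask().astype(int),
            })
            _write_tsv(grand, out / f"diag_{cond}_group.tsv")
            record(st, out / f"diag_{cond}_clusters.json", out / f"diag_{cond}_group.tsv")
            state[f"diag_{cond}"] = courses
            state[f"diag_{cond}_cluster"] = res

    elif name == "tg_within":
        for ci, cond in enumerate(("perception", "imagery")):
            mats = [
                TemporalDecoder(getattr(subj, cond), **kw).fit(
                    seed=derive_seed(config.seed, 1, i)
                )
                for i, subj in enumerate(group)
            ]
            acc = np.stack([m.accuracy for m in mats])
            res = cluster_permutation_vs_chance(
                acc, 0.5, n_perm=n_perm, cluster_alpha=alpha,
                seed=derive_seed(config.seed, 3, ci),
            )
            res.to_json(out / f"tg_{cond}_clusters.json")
            _write_tsv(
                _matrix_frame(mats[0].train_times, mats[0].test_times,
                              acc.mean(axis=0), "train_time_s"),
                out / f"tg_{cond}_group.tsv", index=True,
            )
            record(st, out / f"tg_{cond}_clusters.json", out / f"tg_{cond}_group.tsv")
            state[f"tg_{cond}"] = mats
            state[f"tg_{cond}_cluster"] = res

    elif name == "tg_cross":
        # always both directions (perception->imagery and the reverse)
        for ci, (train_cond, test_cond) in enumerate(
                (("perception", "imagery"), ("imagery", "perception"))):
            mats = [
                TemporalDecoder(getattr(s, train_cond), getattr(s, test_cond), **kw).fit(
                    seed=derive_seed(config.seed, 1, i)
                )
                for i, s in enumerate(group)
            ]
            acc = np.stack([m.accuracy for m in mats])
            res = cluster_permutation_vs_chance(
                acc, 0.5, n_perm=n_perm, cluster_alpha=alpha,
                seed=derive_seed(config.seed, 4, ci),
            )
            tag = f"cross_{train_cond}_to_{test_cond}"
            res.to_json(out / f"{tag}_clusters.json")
            _write_tsv(
                _matrix_frame(mats[0].train_times, mats[0].test_times,
                              acc.mean(axis=0), "train_time_s"),
                out / f"{tag}_group.tsv", index=True,
            )
            record(st, out / f"{tag}_clusters.json", out / f"{tag}_group.tsv")
            state[tag] = mats

    elif name == "specificity":
        for ci, cond in enumerate(("perception", "imagery")):
            spec = specificity_index(
                state[f"tg_{cond}"], state[f"diag_{cond}_cluster"], alpha=alpha,
                n_perm=n_perm, seed=derive_seed(config.seed, 5, ci),
            )
            df = pd.DataFrame({
                "time_s": spec.times,
                "proportion": spec.proportion,
                "in_window": spec.window_mask.astype(int),
            })
            _write_tsv(df, out / f"specificity_{cond}.tsv")
            record(st, out / f"specificity_{cond}.tsv")
            st[f"mean_{cond}"] = None if np.isnan(spec.mean()) else round(spec.mean(), 4)

    elif name == "eyetrack":
        courses = [
            decode_eyetrack(s, seed=derive_seed(config.seed, 1, i), **kw)
            for i, s in enumerate(group)
        ]
        maps = np.stack([c.accuracy for c in courses])
        res = cluster_permutation_vs_chance(
            maps, 0.5, n_perm=n_perm, cluster_alpha=alpha,
            seed=derive_seed(config.seed, 6),
        )
        res.to_json(out / "eyetrack_clusters.json")
        _write_tsv(
            pd.DataFrame({"time_s": courses[0].times, "accuracy": maps.mean(axis=0),
                          "significant": res.mask().astype(int)}),
            out / "eyetrack_group.tsv",
        )
        # does eye decoding explain brain decoding? subject-level correlation
        brain = np.stack([c.accuracy for c in state["diag_perception"]]).mean(axis=1)
        r, p = correlation_test(maps.mean(axis=1), brain, n_perm=n_perm,
                                seed=derive_seed(config.seed, 7))
        (out / "eyetrack_brain_correlation.json").write_text(
            json.dumps({"r": r, "p": p, "n": len(group)}, sort_keys=True)
        )
        record(st, out / "eyetrack_clusters.json", out / "eyetrack_group.tsv",
               out / "eyetrack_brain_correlation.json")

    elif name == "vividness_split":
        maps = np.stack([c.accuracy for c in state["diag_imagery"]])
        vividness = [s.vividness for s in group]
        high, low, res = median_split_compare(
            maps, vividness, n_perm=n_perm, cluster_alpha=alpha,
            seed=derive_seed(config.seed, 8),
        )
        res.to_json(out / "vividness_split_clusters.json")
        (out / "vividness_split_groups.json").write_text(json.dumps({
            "high": [group[i].perception.subject_id for i in high],
            "low": [group[i].perception.subject_id for i in low],
            "mean_vividness_high": float(np.mean([np.mean(vividness[i]) for i in high])),
            "mean_vividness_low": float(np.mean([np.mean(vividness[i]) for i in low])),
        }, sort_keys=True))
        record(st, out / "vividness_split_clusters.json", out / "vividness_split_groups.json")

    elif name == "source":
        region_rows = []
        for i, subj in enumerate(group):
            bf = LCMVBeamformer(subj.leadfield, config.source_cov_window)
            est = bf.fit(subj.perception, config.source_power_window,
                         n_perm=config.source_n_perm,
                         seed=derive_seed(config.seed, 9, i))
            regions = atlas_average(est.corrected, subj.leadfield.region_labels)
            region_rows.append(regions)
        all_regions = sorted({r for row in region_rows for r in row})
        df = pd.DataFrame(
            [[row.get(r, np.nan) for r in all_regions] for row in region_rows],
            columns=[f"region_{r}" for r in all_regions],
        )
        df.insert(0, "subject", [s.perception.subject_id for s in group])
        _write_tsv(df, out / "source_regions.tsv")
        group_mean = df.drop(columns="subject").mean(axis=0)
        _write_tsv(group_mean.rename("corrected_power").to_frame().reset_index(
            names="region"), out / "source_regions_group.tsv")
        record(st, out / "source_regions.tsv", out / "source_regions_group.tsv")

    else:  # pragma: no cover - guarded by RunConfig validation
        raise ValueError(name)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def report(run_dir: str | Path, train_time_slices: int = 4) -> Path:
    """Render figures and a plain-text summary from a completed run directory.

    Regeneration is idempotent; missing stage outputs produce a partial
    report with warnings rather than an error.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run = Path(run_dir)
    manifest = json.loads((run / "manifest.json").read_text())
    lines = [f"tgdecode run report  (config {manifest['config_hash']})", ""]
    warnings_ = []

    for cond in ("perception", "imagery"):
        diag = run / f"diag_{cond}_group.tsv"
        if not diag.exists():
            continue
        df = pd.read_csv(diag, sep="\t")
        fig, ax = plt.subplots(figsize=(6, 3))
        ax.plot(df["time_s"], df["accuracy"], color="k")
        ax.fill_between(df["time_s"], df["accuracy"] - df["sem"],
                        df["accuracy"] + df["sem"], alpha=0.3, color="k")
        sig = df["significant"].astype(bool)
        if sig.any():
            ax.plot(df["time_s"][sig], df["accuracy"][sig], lw=3, color="C3")
        ax.axhline(0.5, ls=":", color="gray")
        ax.set(xlabel="time (s)", ylabel="accuracy", title=f"Diagonal decoding: {cond}")
        fig.tight_layout()
        fig.savefig(run / f"fig_diag_{cond}.png", dpi=110)
        plt.close(fig)
        n_sig = int(sig.sum())
        lines.append(f"diagonal {cond}: peak accuracy "
                     f"{df['accuracy'].max():.3f}, {n_sig} significant time points")

    for tag in ("tg_perception", "tg_imagery", "cross_perception_to_imagery",
                "cross_imagery_to_perception"):
        mat = run / f"{tag}_group.tsv"
        clus = run / f"{tag}_clusters.json"
        if not mat.exists():
            continue
        df = pd.read_csv(mat, sep="\t", index_col=0)
        acc = df.to_numpy()
        fig, ax = plt.subplots(figsize=(4.6, 4))
        extent = [float(df.columns[0]), float(df.columns[-1]),
                  df.index[-1], df.index[0]]
        im = ax.imshow(acc, aspect="auto", extent=extent, cmap="RdBu_r",
                       vmin=0.5 - abs(acc - 0.5).max(), vmax=0.5 + abs(acc - 0.5).max())
        if clus.exists():
            cj = json.loads(clus.read_text())
            mask = np.zeros(acc.shape, dtype=bool)
            for c in cj["clusters"]:
                if c["p_value"] < cj["alpha"]:
                    idx = np.asarray(c["members"])
                    mask[idx[:, 0], idx[:, 1]] = True
            if mask.any():
                ax.contour(np.linspace(extent[0], extent[1], acc.shape[1]),
                           df.index, mask.astype(float), levels=[0.5], colors="k")
            n_sig_cl = sum(c["p_value"] < cj["alpha"] for c in cj["clusters"])
            lines.append(f"{tag}: {len(cj['clusters'])} clusters, {n_sig_cl} significant")
        ax.set(xlabel="test time (s)", ylabel="train time (s)", title=tag)
        fig.colorbar(im, ax=ax, label="accuracy")
        fig.tight_layout()
        fig.savefig(run / f"fig_{tag}.png", dpi=110)
        plt.close(fig)

        # cross-decoding accuracy at selected training times (figure-panel style)
        if tag.startswith("cross_"):
            rows = np.linspace(0, acc.shape[0] - 1, train_time_slices).astype(int)
            fig, axes = plt.subplots(len(rows), 1, figsize=(5, 1.6 * len(rows)),
                                     sharex=True)
            for ax2, r in zip(np.atleast_1d(axes), rows):
                ax2.plot([float(c) for c in df.columns], acc[r], color="k")
                ax2.axhline(0.5, ls=":", color="gray")
                ax2.set_ylabel(f"train {df.index[r]:.2f}s", fontsize=8)
            fig.suptitle(f"{tag}: training-time slices")
            fig.tight_layout()
            fig.savefig(run / f"fig_{tag}_slices.png", dpi=110)
            plt.close(fig)

    spec_files = sorted(run.glob("specificity_*.tsv"))
    for f in spec_files:
        df = pd.read_csv(f, sep="\t")
        cond = f.stem.replace("specificity_", "")
        fig, ax = plt.subplots(figsize=(6, 2.5))
        ax.plot(df["time_s"], df["proportion"], color="k")
        ax.set(xlabel="time (s)", ylabel="specificity", ylim=(-0.05, 1.05),
               title=f"Temporal specificity: {cond}")
        fig.tight_layout()
        fig.savefig(run / f"fig_specificity_{cond}.png", dpi=110)
        plt.close(fig)
        in_w = df["in_window"].astype(bool)
        if in_w.any():
            lines.append(f"specificity {cond}: mean {df['proportion'][in_w].mean():.3f} "
                         f"over {int(in_w.sum())} window points")

    for name, info in manifest["stages"].items():
        if info.get("status") not in ("ok", None):
            if info["status"] != "ok":
                warnings_.append(f"stage {name}: {info['status']}")
    if warnings_:
        lines += ["", "WARNINGS:"] + [f"  {w}" for w in warnings_]

    summary = run / "report.txt"
    summary.write_text("\n".join(lines) + "\n")
    return summary
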