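"""Summary statistics, Pr heatmaps, and the end-to-end pipeline runner."""

from __future__ import annotations

import platform
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
from scipy import stats

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402  (backend must be set first)

from . import io, puncta, quantal, simulate, timestamp, turnover  # noqa: E402


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""


def pearson_r(x, y) -> float:
    """Product-moment correlation; requires >= 3 finite pairs and variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length series with at least 3 points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("series must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance series")
    return float(stats.pearsonr(x, y)[0])


def group_compare(values_a, values_b, *, welch: bool = True) -> dict:
    """Two-group summary: means +/- SEM, fold change, two-sample t test."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return {
        "mean_a": float(a.mean()), "sem_a": float(stats.sem(a)),
        "mean_b": float(b.mean()), "sem_b": float(stats.sem(b)),
        "fold": float(a.mean() / b.mean()) if b.mean() != 0 else float("nan"),
        "t": float(t), "p": float(p),
        "n_a": len(a), "n_b": len(b),
    }


def roi_values(rmap: quantal.ReleaseMap, rois: quantal.ROISet,
               value: str = "pr") -> np.ndarray:
    """Release-map column aligned to the ROI set's id order."""
    if len(rmap.table) != len(rois):
        raise ValueError("release map and ROI set are inconsistent")
    return (rmap.table.set_index("roi_id").loc[rois.ids, value]
            .to_numpy(dtype=float))


def render_pr_heatmap(rmap: quantal.ReleaseMap, rois: quantal.ROISet,
                      background: np.ndarray, path, *,
                      value: str = "pr", pixel_size: float | None = None,
                      cmap: str = "inferno") -> None:
    """ROIs colored by Pr (or spontaneous rate) over a projected background."""
    px = pixel_size or 1.0
    vals = roi_values(rmap, rois, value)
    fig, ax = plt.subplots(figsize=(6, 6 * background.shape[0]
                                    / max(1, background.shape[1])))
    ax.imshow(background, cmap="gray",
              extent=(0, background.shape[1] * px,
                      background.shape[0] * px, 0))
    sc = ax.scatter(rois.centers[:, 0], rois.centers[:, 1], c=vals,
                    cmap=cmap, s=80, edgecolors="white", linewidths=0.5,
                    vmin=0.0, vmax=max(vals.max(), 1e-9))
    fig.colorbar(sc, ax=ax, label=value)
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

_DEFAULT_CONFIG = {
    "seed": 0,
    "outdir": "quantalmap_out",
    "pixel_size": simulate.DEFAULT_PIXEL_SIZE,
    "geometry": {"n_boutons": 4, "az_per_bouton": 12},
    "movie": {},
    "detection": {},
    "photoconversion": None,  # e.g. {"half_life_days": 2.2, "timepoints": [0, 1]}
}


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"[{name}] {exc}") from exc
        return wrapper
    return deco


def run_pipeline(config: dict | str | Path) -> dict:
    """Simulate -> puncta -> quantal -> timestamp (-> turnover) -> report.

    ``config`` is a mapping (or YAML path) with the keys of
    ``_DEFAULT_CONFIG``; everything is seeded, and the run log written to the
    output directory records parameters, versions and outputs so a rerun
    reproduces every file.
    """
    if not isinstance(config, dict):
        config = io.load_config(config)
    cfg = {**_DEFAULT_CONFIG, **config}
    seed = int(cfg["seed"])
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    px = float(cfg["pixel_size"])
    results: dict = {"outputs": {}}

    @_stage("simulate")
    def _simulate():
        gt = simulate.make_geometry(seed=seed, pixel_size=px,
                                    **cfg["geometry"])
        spec = simulate.MovieSpec(**cfg["movie"])
        movie, events_true, info = simulate.simulate_quantal_movie(
            gt, spec, seed=seed)
        io.write_ground_truth_csv(outdir / "ground_truth.csv", gt)
        io.write_movie_tiff(outdir / "movie.tif", movie)
        az_stack = simulate.render_puncta_stack(gt, "az", seed=seed)
        io.write_stack_tiff(outdir / "az_stack.tif", az_stack)
        return gt, movie, events_true, info, az_stack

    gt, movie, events_true, info, az_stack = _simulate()

    @_stage("puncta")
    def _puncta():
        plane = puncta.max_project(az_stack)
        pset = puncta.detect_puncta(plane, px, nmj_id="sim", channel="az")
        pset.to_frame().to_csv(outdir / "az_puncta.csv", index=False)
        return plane, pset

    plane, az_set = _puncta()

    @_stage("quantal")
    def _quantal():
        rois = quantal.ROISet(np.arange(gt.n_az), gt.az_centroids,
                              source_channel="az")
        rmap, events = quantal.map_movie(
            movie, rois, px, info["n_stimulations"], info["duration"],
            **cfg["detection"])
        quantal.events_to_frame(events).to_csv(outdir / "events.csv",
                                               index=False)
        rmap.table.to_csv(outdir / "release_map.csv", index=False)
        render_pr_heatmap(rmap, rois, plane, outdir / "pr_heatmap.png",
                          pixel_size=px)
        return rois, rmap, events

    rois, rmap, events = _quantal()
    results["release_map"] = rmap
    results["n_events"] = len(events)

    @_stage("timestamp")
    def _timestamp():
        red = simulate.render_puncta_stack(gt, "glur_red", seed=seed)
        green = simulate.render_puncta_stack(gt, "glur_green", seed=seed + 1)
        table, pset = timestamp.measure_psd_channels(red, green, px)
        labels = timestamp.classify_age(table)
        pairing = puncta.opposition_pairs(az_set, pset)
        stats_out = timestamp.age_output_correlation(labels, rmap.table,
                                                     pairing)
        labels.to_csv(outdir / "psd_age.csv", index=False)
        return stats_out

    results["age_stats"] = _timestamp()

    if cfg.get("photoconversion"):
        @_stage("turnover")
        def _turnover():
            pc = dict(cfg["photoconversion"])
            series = simulate.simulate_photoconversion_series(
                gt, pc.pop("half_life_days"), pc.pop("timepoints"),
                seed=seed, **pc)
            res = turnover.estimate_turnover(series, px)
            pd.DataFrame([res.__dict__]).to_csv(outdir / "turnover.csv",
                                                index=False)
            return res

        results["turnover"] = _turnover()

    io.write_run_log(outdir / "run_log.json", {
        "config": cfg,
        "seed": seed,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": sorted(p.name for p in outdir.iterdir()),
        "summary": rmap.summary,
    })
    results["outdir"] = outdir
    return results
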