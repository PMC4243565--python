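"""Preset experiment recipes and the run driver.

Each preset bundles the exact parameter set of one published protocol
(spontaneous repeated sequences, neuronal avalanches at several system
sizes, evoked sequences with spontaneous replay, receptive-field emergence
from images, and the integrate-and-fire f-I sanity check), together with the
stimulus construction and the analyses to run afterwards.  Full-scale runs
use the printed parameter blocks verbatim; scaled runs change only the step
counts and logging cadence.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .config import LearningConfig, NetworkConfig
from .learning import InfomaxTrainer
from .network import SpikeRaster, lif_fi_curve, simulate, split_streams
from .stimuli import (
    EpisodicSequenceConfig,
    EpisodicSequenceStream,
    ImageSet,
    OnOffEncoderConfig,
    OnOffImageStream,
    calibrate_xi,
    synthetic_image_fixture,
    whiten_images,
)

__all__ = ["ExperimentPreset", "PRESETS", "run_preset", "rf_grid_image", "lif_check_table"]


@dataclass(frozen=True)
class ExperimentPreset:
    """One named experiment recipe at full or scaled problem size."""

    name: str
    net: NetworkConfig
    learn: LearningConfig
    stimulus: Optional[str] = None  # None | "episodic" | "images"
    full_steps: int = 2_000_000_000
    scaled_steps: int = 1_000_000
    analysis_window: int = 50_000
    n_shuffles: int = 100
    feedforward_init: float = 100.0
    notes: str = ""


def _spontaneous_sequences() -> ExperimentPreset:
    return ExperimentPreset(
        name="spontaneous-sequences",
        net=NetworkConfig(n_neurons=50, p_max=0.95, p0=0.05),
        learn=LearningConfig(epsilon=0.006, c_eta=1.5, c_kappa=1.0, c_zeta=3.0, tau=15.0, T=50000.0),
        notes="repeated precise firing sequences in spontaneous activity",
    )


def _avalanches(variant: int = 0) -> ExperimentPreset:
    variants = [
        # (eps, c_eta, c_kappa, c_zeta, p0, p_max, N, tau)
        (0.02, 10.0, 30.0, 3.0, 0.01, 0.4, 50, 10.0),
        (0.02, 10.0, 30.0, 3.0, 0.01, 0.2, 50, 10.0),
        (0.02, 10.0, 30.0, 3.0, 0.01, 0.8, 50, 10.0),
        (0.01, 20.0, 60.0, 4.0, 0.005, 0.2, 100, 15.0),
        (0.006, 40.0, 100.0, 6.0, 0.0025, 0.2, 200, 20.0),
        (0.005, 3.0, 1.0, 10.0, 0.01, 0.95, 50, 20.0),
    ]
    eps, c_eta, c_kappa, c_zeta, p0, p_max, n, tau = variants[variant]
    return ExperimentPreset(
        name="avalanches",
        net=NetworkConfig(n_neurons=n, p_max=p_max, p0=p0),
        learn=LearningConfig(
            epsilon=eps, c_eta=c_eta, c_kappa=c_kappa, c_zeta=c_zeta, tau=tau, T=50000.0
        ),
        scaled_steps=10_000_000,
        notes="power-law avalanche size distribution (slope near -3/2)",
    )


def _evoked_replay() -> ExperimentPreset:
    n = 50
    return ExperimentPreset(
        name="evoked-replay",
        net=NetworkConfig(n_neurons=n, p_max=0.98, p0=0.02, n_external=3),
        learn=LearningConfig(
            epsilon=0.01, c_eta=2.0, c_kappa=3.0, c_zeta=10.0, tau=15.0, T=50000.0
        ),
        stimulus="episodic",
        notes="evoked firing sequences and their spontaneous replays",
    )


def _receptive_fields() -> ExperimentPreset:
    side = 12
    n_lgn = 2 * side * side
    return ExperimentPreset(
        name="receptive-fields",
        net=NetworkConfig(n_neurons=100, p_max=0.95, p0=0.0015, n_external=n_lgn),
        learn=LearningConfig(
            epsilon=0.02, c_eta=250.0, c_kappa=150.0, c_zeta=1000.0, tau=5.0, T=50000.0
        ),
        stimulus="images",
        notes="simple-cell-like receptive fields from ON/OFF-encoded patches",
    )


def _lif_check() -> ExperimentPreset:
    return ExperimentPreset(
        name="lif-check",
        net=NetworkConfig(n_neurons=1, p_max=0.95, p0=0.05),
        learn=LearningConfig(),
        notes="integrate-and-fire f-I curves motivating the sigmoid transfer",
    )


PRESETS = {
    "spontaneous-sequences": _spontaneous_sequences,
    "avalanches": _avalanches,
    "evoked-replay": _evoked_replay,
    "receptive-fields": _receptive_fields,
    "lif-check": _lif_check,
}


def _make_stimulus(preset: ExperimentPreset, rng: np.random.Generator, log_patches: bool = False):
    if preset.stimulus is None:
        return None, None
    if preset.stimulus == "episodic":
        return EpisodicSequenceStream(EpisodicSequenceConfig(), rng), None
    if preset.stimulus == "images":
        img_rng, stream_rng = (np.random.default_rng(s) for s in rng.integers(0, 2**31, 2))
        fixture = whiten_images(synthetic_image_fixture(n_images=10, side=128, rng=img_rng))
        enc = OnOffEncoderConfig(xi=calibrate_xi(fixture, target_rate=0.15, rng=img_rng))
        return OnOffImageStream(fixture, enc, stream_rng, log_patches=log_patches), fixture
    raise ValueError(f"unknown stimulus kind {preset.stimulus!r}")


def lif_check_table(
    currents=None, t_refs=(1.0, 2.0, 3.0), duration: float = 5000.0, seed: int = 0
):
    """f-I table of the noisy integrate-and-fire model: one column of firing
    frequencies (cycles/ms) per refractory period, over the current sweep."""
    if currents is None:
        currents = np.arange(-200.0, 601.0, 25.0)
    currents = np.asarray(currents, dtype=np.float64)
    rows = {}
    for k, t_ref in enumerate(t_refs):
        rng = np.random.default_rng(np.random.SeedSequence([seed, k]))
        rows[t_ref] = lif_fi_curve(currents, t_ref=t_ref, duration=duration, rng=rng)
    return currents, rows


def rf_grid_image(rfmap, side: int = 12, n_cols: int = 10, gap: int = 2) -> np.ndarray:
    """Tile the rescaled receptive-field patches into one uint8 grid image."""
    keys = sorted(rfmap.rescaled)
    n = len(keys)
    if n == 0:
        return np.full((side, side), 128, dtype=np.uint8)
    n_rows = (n + n_cols - 1) // n_cols
    H = n_rows * side + (n_rows - 1) * gap
    W = n_cols * side + (n_cols - 1) * gap
    grid = np.zeros((H, W), dtype=np.uint8)
    for k, i in enumerate(keys):
        r, c = divmod(k, n_cols)
        patch = np.clip(np.rint(rfmap.rescaled[i].reshape(side, side)), 1, 255)
        grid[
            r * (side + gap) : r * (side + gap) + side,
            c * (side + gap) : c * (side + gap) + side,
        ] = patch.astype(np.uint8)
    return grid


def run_preset(
    preset,
    output_dir,
    seed: int = 0,
    scale: str | float = "scaled",
    log_every: Optional[int] = None,
    avalanche_variant: int = 0,
) -> dict:
    """Execute train -> simulate -> analyses for a preset; returns the manifest.

    ``scale`` is "full", "scaled" or a float factor applied to the full step
    count.  Outputs (config, metrics, parameter snapshots, rasters, analysis
    CSVs and the manifest) land in ``output_dir``.
    """
    from . import analysis as ana
    from . import io as io_mod

    if isinstance(preset, str):
        factory = PRESETS[preset]
        preset = factory(avalanche_variant) if preset == "avalanches" else factory()
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "analysis").mkdir(exist_ok=True)
    started = time.time()

    manifest: dict = {
        "preset": preset.name,
        "seed": int(seed),
        "version": __version__,
        "outputs": {},
        "status": "running",
    }

    if preset.name == "lif-check":
        currents, rows = lif_check_table(seed=seed)
        import pandas as pd

        df = pd.DataFrame({"I_mV": currents})
        for t_ref, freqs in rows.items():
            df[f"f_tref_{t_ref:g}ms"] = freqs
        path = out / "analysis" / "fi_curves.csv"
        df.to_csv(path, index=False)
        manifest["outputs"]["fi_curves"] = str(path)
        manifest["status"] = "done"
        manifest["wall_seconds"] = time.time() - started
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest

    if scale == "full":
        n_steps = preset.full_steps
    elif scale == "scaled":
        n_steps = preset.scaled_steps
    else:
        n_steps = max(int(preset.full_steps * float(scale)), 1)
    if log_every is None:
        log_every = max(n_steps // 20, 10_000)

    io_mod.save_config(out / "config.yaml", preset.net, preset.learn, seed)
    manifest["config_hash"] = hashlib.sha256((out / "config.yaml").read_bytes()).hexdigest()

    _, _, stim_rng = split_streams(seed, 3)
    stimulus, _ = _make_stimulus(preset, stim_rng)
    trainer = InfomaxTrainer(preset.net, preset.learn, seed=seed, stimulus_source=stimulus)
    if preset.stimulus == "episodic":
        # designated feedforward pathway: strong initial weights, still plastic
        n = preset.net.n_neurons
        for k in range(preset.net.n_external):
            trainer.params.weights[k, n + k] = preset.feedforward_init

    metrics = trainer.run(n_steps, log_every=log_every, window=preset.analysis_window)
    io_mod.append_metrics(out / "metrics.jsonl", metrics)
    io_mod.save_parameters_h5(out / "weights_final.h5", trainer.params, preset.net, preset.learn, seed)
    manifest["outputs"]["weights"] = str(out / "weights_final.h5")
    manifest["outputs"]["metrics"] = str(out / "metrics.jsonl")

    # post-training analyses on a fresh frozen-parameter window
    _, sim_rng, stim_rng2 = split_streams(seed + 1, 3)
    stimulus2, _ = _make_stimulus(preset, stim_rng2)
    raster = simulate(
        trainer.params,
        preset.analysis_window,
        stimulus_source=stimulus2,
        rng=sim_rng,
        p_max=preset.net.p_max,
    )
    io_mod.save_raster_events(out / "raster_post.tsv", raster)
    manifest["outputs"]["raster"] = str(out / "raster_post.tsv")

    rec = SpikeRaster(spikes=raster.spikes[:, : preset.net.n_neurons])
    results: dict = {}
    try:
        results["i_gauss"] = float(ana.i_gauss(rec, warn_short=False))
    except Exception as e:  # degenerate windows stay reportable
        results["i_gauss"] = None
        results["i_gauss_error"] = str(e)
    results["mean_rate"] = float(rec.spikes.mean())

    if preset.name in ("spontaneous-sequences", "avalanches"):
        catalog = ana.detect_bursts(rec)
        results["n_bursts"] = catalog.n_bursts
        try:
            slope, stderr = ana.fit_power_law_slope(catalog)
            results["burst_slope"] = slope
            results["burst_slope_stderr"] = stderr
        except ValueError as e:
            results["burst_slope_error"] = str(e)
        census = ana.count_patterns_and_sequences(rec, lengths=(2, 3, 5, 10))
        results["census_distinct"] = {str(k): v for k, v in census.distinct.items()}
        results["census_repeated"] = {str(k): v for k, v in census.repeated.items()}
    if preset.name == "spontaneous-sequences":
        # shuffled-weight control: rank of the learned network among networks
        # with the same weight multiset but permuted positions
        n_shuf = preset.n_shuffles if scale == "full" else min(preset.n_shuffles, 10)
        shuf_rng = np.random.default_rng(np.random.SeedSequence([seed, 999]))
        window = min(preset.analysis_window, 20_000)
        orig_census = ana.count_patterns_and_sequences(
            SpikeRaster(spikes=rec.spikes[:window]), lengths=(3,)
        )
        orig_rep = orig_census.repeated[3]
        shuf_reps = []
        for k in range(n_shuf):
            sh = ana.shuffle_weights(trainer.params, shuf_rng)
            sr = simulate(sh, window, rng=np.random.default_rng(np.random.SeedSequence([seed, k])), p_max=preset.net.p_max)
            c = ana.count_patterns_and_sequences(
                SpikeRaster(spikes=sr.spikes[:, : preset.net.n_neurons]), lengths=(3,)
            )
            shuf_reps.append(c.repeated[3])
        results["shuffle_control"] = {
            "repeated_L3_original": orig_rep,
            "repeated_L3_shuffled": shuf_reps,
            "rank_of_original": int(sum(1 for v in shuf_reps if v >= orig_rep)),
        }
    if preset.name == "evoked-replay":
        n = preset.net.n_neurons
        chains = ana.extract_strong_chains(
            trainer.params, roots=[n], threshold=8.0, max_depth=6
        )
        with open(out / "analysis" / "chains.tsv", "w") as f:
            f.write("pre\tpost\tweight\tdepth\n")
            for pre, post, w in chains.edges:
                f.write(f"{pre}\t{post}\t{w:.4f}\t{chains.depths[post]}\n")
        results["chain_nodes"] = len(chains.depths)
        manifest["outputs"]["chains"] = str(out / "analysis" / "chains.tsv")
    if preset.name == "receptive-fields":
        import imageio.v3 as iio

        _, sim_rng3, stim_rng3 = split_streams(seed + 2, 3)
        stimulus3, _ = _make_stimulus(preset, stim_rng3, log_patches=True)
        sta_raster = simulate(
            trainer.params,
            preset.analysis_window,
            stimulus_source=stimulus3,
            rng=sim_rng3,
            p_max=preset.net.p_max,
        )
        patches = np.asarray(stimulus3.patch_log)
        rfmap = ana.spike_triggered_average(
            SpikeRaster(spikes=sta_raster.spikes[:, : preset.net.n_neurons]), patches
        )
        grid = rf_grid_image(rfmap, side=12)
        iio.imwrite(out / "analysis" / "receptive_fields.png", grid)
        results["n_rf_patches"] = len(rfmap.rescaled)
        manifest["outputs"]["receptive_fields"] = str(out / "analysis" / "receptive_fields.png")

    (out / "analysis" / "summary.json").write_text(json.dumps(results, indent=2))
    manifest["outputs"]["summary"] = str(out / "analysis" / "summary.json")
    manifest["status"] = "done"
    manifest["wall_seconds"] = time.time() - started
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
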