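"""End-to-end orchestration: simulate -> detect -> fit-hmm -> label ->
spectra -> evoked -> bursts, with seeded determinism and a summary report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import bursts as bursts_mod
from . import evoked as evoked_mod
from . import geometry, hmm, replay, spectral
from .io import SubjectFixture
from .synthetic import SimConfig, lag_to_samples, resample_path, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "run_all",
    "validate_against_truth",
    "match_event_trains",
    "save_hmm",
    "load_hmm",
]


@dataclass
class HmmConfig:
    K: int = 4
    embed_l: int = 7
    pca_components: int | None = None  # default 2 * n_channels
    n_restarts: int = 5
    max_iter: int = 100
    tol: float = 1e-6


@dataclass
class DetectConfig:
    percentile: float = 99.0
    lag_ms: float = 40.0
    l1_penalty: float = 1.0
    training_time_ms: float | None = 200.0  # None: pick by cross-validation
    n_folds: int = 5


@dataclass
class EvokedConfig:
    window_s: float = 0.5
    t_threshold: float = 3.0
    n_perm: int = 5000


@dataclass
class BurstConfig:
    n_perm: int = 1000
    n_windows: int = 30
    window_lo_s: float = 0.1
    window_hi_s: float = 30.0
    min_obs: int = 10
    min_visits: int = 3

    def grid(self) -> np.ndarray:
        return bursts_mod.default_window_grid(self.n_windows, self.window_lo_s, self.window_hi_s)


@dataclass
class SpectraConfig:
    window_s: float = 2.0
    n_tapers: int = 7
    band: tuple[float, float] = (1.0, 45.0)
    n_modes: int = 2
    nnmf_restarts: int = 10
    hf_band: tuple[float, float] = (1.0, 160.0)
    hf_window_ms: float = 30.0
    hf_ripple_band: tuple[float, float] = (102.0, 148.0)


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    hmm: HmmConfig = field(default_factory=HmmConfig)
    detect: DetectConfig = field(default_factory=DetectConfig)
    evoked: EvokedConfig = field(default_factory=EvokedConfig)
    bursts: BurstConfig = field(default_factory=BurstConfig)
    spectra: SpectraConfig = field(default_factory=SpectraConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        sections = {
            "sim": SimConfig, "hmm": HmmConfig, "detect": DetectConfig,
            "evoked": EvokedConfig, "bursts": BurstConfig, "spectra": SpectraConfig,
        }
        for name, klass in sections.items():
            if name in raw:
                base = dataclasses.asdict(getattr(cfg, name))
                base.update(raw[name])
                fields = {f.name for f in dataclasses.fields(klass)}
                unknown = set(base) - fields
                if unknown:
                    raise ValueError(f"unknown keys in [{name}]: {sorted(unknown)}")
                # restore tuple-typed fields mangled by yaml lists
                for k, v in base.items():
                    if isinstance(v, list):
                        base[k] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
                setattr(cfg, name, klass(**base))
        if "seed" in raw:
            cfg.seed = int(raw["seed"])
        return cfg


def save_hmm(path: str | Path, model: hmm.HmmModel, stcs: list[hmm.StateTimecourse]) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("hmm")
        g.create_dataset("covariances", data=model.covariances)
        g.create_dataset("transition", data=model.transition)
        g.create_dataset("initial", data=model.initial)
        g.create_dataset("objective", data=model.objective)
        g.create_dataset("embed_l", data=model.embedding.l)
        g.create_dataset("pca_components", data=model.embedding.pca_components or -1)
        if model.pca_basis is not None:
            g.create_dataset("pca_basis", data=model.pca_basis)
        for i, stc in enumerate(stcs):
            sg = f.create_group(f"gamma/subject_{i:02d}")
            sg.create_dataset("gamma", data=stc.gamma)
            sg.create_dataset("viterbi", data=stc.viterbi)
            sg.create_dataset("valid_range", data=np.asarray(stc.valid_range))


def load_hmm(path: str | Path) -> tuple[hmm.HmmModel, list[hmm.StateTimecourse]]:
    with h5py.File(path, "r") as f:
        g = f["hmm"]
        pca = int(g["pca_components"][()])
        model = hmm.HmmModel(
            K=g["covariances"].shape[0],
            covariances=g["covariances"][...],
            transition=g["transition"][...],
            initial=g["initial"][...],
            embedding=hmm.EmbeddingConfig(
                l=int(g["embed_l"][()]), pca_components=None if pca < 0 else pca
            ),
            pca_basis=g["pca_basis"][...] if "pca_basis" in g else None,
            objective=float(g["objective"][()]),
        )
        stcs = []
        if "gamma" in f:
            for name in sorted(f["gamma"]):
                sg = f["gamma"][name]
                stcs.append(
                    hmm.StateTimecourse(
                        gamma=sg["gamma"][...],
                        viterbi=sg["viterbi"][...],
                        valid_range=tuple(int(x) for x in sg["valid_range"][...]),
                    )
                )
    return model, stcs


def detect_subject(
    fixture: SubjectFixture, cfg: DetectConfig, seed: int = 0
) -> tuple[replay.ReplayEventTrain, replay.ReactivationProbabilities, replay.ClassifierSet]:
    """Localizer training -> reactivation probabilities -> R_t -> events."""
    if cfg.training_time_ms is None:
        time_ms = replay.pick_training_time(
            fixture.localizer, cfg.l1_penalty, cfg.n_folds, seed=seed
        ).time_ms
    else:
        time_ms = cfg.training_time_ms
    classifiers = replay.train_classifiers(fixture.localizer, time_ms, cfg.l1_penalty)
    probs = replay.apply_classifiers(fixture.session, classifiers)
    tau = lag_to_samples(cfg.lag_ms, fixture.session.fs)
    sequences = fixture.sequences or ((0, 1, 2, 3), (4, 5, 6, 7))
    trace = replay.replay_probability(probs, sequences, tau)
    train = replay.threshold_events(
        trace, fixture.session.fs, cfg.percentile,
        bad_mask=fixture.session.bad_mask, lag_samples=tau,
    )
    return train, probs, classifiers


def fit_group_hmm(
    fixtures: list[SubjectFixture], cfg: HmmConfig, seed: int = 0
) -> tuple[hmm.HmmModel, list[hmm.StateTimecourse]]:
    """Fit one model on all subjects (shared PCA basis, chains broken at
    subject boundaries), then decode each subject."""
    l = cfg.embed_l
    embedded = []
    valids = []
    ranges = []
    for fx in fixtures:
        E, valid, vr = hmm.embed(fx.session, l)
        embedded.append(E)
        valids.append(valid)
        ranges.append(vr)
    n_comp = cfg.pca_components or 2 * fixtures[0].session.n_channels
    # shared basis from the pooled embedded covariance
    D = embedded[0].shape[0]
    cov = np.zeros((D, D))
    total = 0
    for E, valid in zip(embedded, valids):
        X = E[:, valid]
        cov += X @ X.T
        total += X.shape[1]
    cov /= total
    evals, evecs = np.linalg.eigh(cov)
    basis = evecs[:, ::-1][:, :n_comp]
    reduced = [basis.T @ E for E in embedded]
    # concatenate with a one-frame invalid separator between subjects
    gap = np.zeros((n_comp, 1))
    parts, vparts = [], []
    for i, (R, valid) in enumerate(zip(reduced, valids)):
        parts.append(R)
        vparts.append(valid)
        if i < len(reduced) - 1:
            parts.append(gap)
            vparts.append(np.array([False]))
    R_all = np.concatenate(parts, axis=1)
    v_all = np.concatenate(vparts)
    embedding = hmm.EmbeddingConfig(l=l, pca_components=n_comp)
    model, _ = hmm.fit(
        R_all, v_all, cfg.K, n_restarts=cfg.n_restarts, max_iter=cfg.max_iter,
        tol=cfg.tol, seed=seed, embedding=embedding, pca_basis=basis,
    )
    stcs = [
        hmm.decode(model, R, valid, valid_range=vr)
        for R, valid, vr in zip(reduced, valids, ranges)
    ]
    return model, stcs


def match_event_trains(
    detected: np.ndarray, planted: np.ndarray, tol_samples: int = 2
) -> tuple[float, float]:
    """Greedy one-to-one matching within a tolerance; returns
    (precision, recall)."""
    detected = np.asarray(detected)
    planted = np.asarray(planted)
    if detected.size == 0 or planted.size == 0:
        return 0.0, 0.0
    used = np.zeros(planted.size, dtype=bool)
    hits = 0
    for d in detected:
        diffs = np.abs(planted - d)
        diffs[used] = np.iinfo(np.int64).max
        j = int(np.argmin(diffs))
        if diffs[j] <= tol_samples:
            used[j] = True
            hits += 1
    return hits / detected.size, hits / planted.size


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

        return wrapper

    return deco


def run_all(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage and write artifacts plus ``summary.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config
    if cfg.sim.n_subjects < 3:
        raise ValueError("group statistics need at least 3 subjects")
    summary: dict = {"seed": cfg.seed, "n_subjects": cfg.sim.n_subjects}

    sim_cfg = dataclasses.replace(cfg.sim, base_seed=cfg.seed)
    fixtures = _stage("simulate")(simulate_dataset)(sim_cfg)
    fs = fixtures[0].session.fs
    T = fixtures[0].session.n_samples

    # --- detection ---
    trains, probs_list = [], []
    for i, fx in enumerate(fixtures):
        train, probs, _ = _stage("detect")(detect_subject)(fx, cfg.detect, seed=cfg.seed + i)
        trains.append(train)
        probs_list.append(probs)
    frames = [replay.events_to_frame(t, i) for i, t in enumerate(trains)]
    pd.concat(frames).to_csv(out / "events.tsv", sep="\t", index=False)
    summary["n_events"] = [int(t.event_onsets.size) for t in trains]

    # --- hmm ---
    model, stcs = _stage("fit-hmm")(fit_group_hmm)(fixtures, cfg.hmm, seed=cfg.seed)
    save_hmm(out / "hmm.h5", model, stcs)
    summary["hmm_objective"] = model.objective

    # --- labeling / geometry ---
    dist = _stage("label")(geometry.transition_distance)(model.transition)
    order = geometry.mds_order(dist)
    visit_stats = [
        geometry.visit_statistics(
            stc.viterbi_full(T), fs, fx.session.bad_mask, K=model.K
        )
        for stc, fx in zip(stcs, fixtures)
    ]
    occ = np.mean([vs.occupancy for vs in visit_stats], axis=0)
    labels_df = pd.DataFrame(
        {
            "state_label": order.labels,
            "raw_state": np.arange(model.K),
            "mds_coord": order.coords,
            "mean_lifetime_ms": [
                1000 * np.nanmean([vs.mean_lifetimes()[k] for vs in visit_stats])
                for k in range(model.K)
            ],
            "mean_interval_s": [
                np.nanmean([vs.mean_intervals()[k] for vs in visit_stats])
                for k in range(model.K)
            ],
            "occupancy": occ,
        }
    )
    labels_df.to_csv(out / "state_labels.tsv", sep="\t", index=False)
    summary["occupancy"] = occ.tolist()

    # --- spectra ---
    def spectra_stage():
        per_subj = [
            spectral.state_multitaper(
                fx.session, stc.viterbi_full(T), K=model.K,
                window_s=cfg.spectra.window_s, n_tapers=cfg.spectra.n_tapers,
                band=cfg.spectra.band,
            )
            for fx, stc in zip(fixtures, stcs)
        ]
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            mean_psd = np.nanmean([s.psd for s in per_subj], axis=0)
            mean_coh = np.nanmean([s.coherence for s in per_subj], axis=0)
        group = spectral.StateSpectra(
            psd=mean_psd, coherence=mean_coh, freqs=per_subj[0].freqs,
            params=per_subj[0].params,
        )
        try:
            modes = spectral.nnmf_modes(
                group, cfg.spectra.n_modes, cfg.spectra.nnmf_restarts, seed=cfg.seed
            )
        except ValueError as exc:
            logger.warning("spectral mode decomposition skipped: %s", exc)
            modes = None
        return group, modes

    group_spectra, modes = _stage("spectra")(spectra_stage)()
    summary["state_peak_freq_hz"] = [
        float(group_spectra.freqs[int(np.argmax(np.nanmean(group_spectra.psd[k], axis=0)))])
        if np.isfinite(group_spectra.psd[k]).any()
        else None
        for k in range(model.K)
    ]
    summary["mode_centroids_hz"] = None if modes is None else modes.centroids().tolist()

    # --- evoked ---
    def evoked_stage():
        subj = []
        for fx, stc, train in zip(fixtures, stcs, trains):
            subj.append(
                evoked_mod.epoch_states(
                    stc.gamma_full(T), train.event_onsets, fs,
                    cfg.evoked.window_s, True, fx.session.bad_mask,
                )
            )
        resp = evoked_mod.EvokedResponse.stack(subj)
        clusters = evoked_mod.cluster_permutation(
            resp, cfg.evoked.t_threshold, cfg.evoked.n_perm, seed=cfg.seed
        )
        return resp, clusters

    resp, clusters = _stage("evoked")(evoked_stage)()
    cluster_rows = [
        {
            "state": c.state, "lag_start_s": c.lag_start_s, "lag_end_s": c.lag_end_s,
            "mass": c.mass, "p": c.p,
        }
        for c in clusters.clusters
    ]
    pd.DataFrame(cluster_rows, columns=["state", "lag_start_s", "lag_end_s", "mass", "p"]).to_csv(
        out / "clusters.tsv", sep="\t", index=False
    )
    lag0 = resp.values.shape[1] // 2
    summary["evoked_lag0_mean"] = resp.values[:, lag0, :].mean(axis=1).tolist()
    summary["clusters"] = cluster_rows

    # --- bursts ---
    def bursts_stage():
        grid = cfg.bursts.grid()
        curves = [
            bursts_mod.fano_curve(t.event_onsets, T, fs, fx.session.bad_mask, grid)
            for t, fx in zip(trains, fixtures)
        ]
        shuffle = bursts_mod.interval_shuffle_test(
            [t.event_onsets for t in trains], T, fs, cfg.bursts.n_perm, grid,
            seed=cfg.seed, bad_masks=[fx.session.bad_mask for fx in fixtures],
        )
        visit_trains = [vs.onsets for vs in visit_stats]
        svf = bursts_mod.state_visit_fano(
            visit_trains, T, fs, grid,
            bad_masks=[fx.session.bad_mask for fx in fixtures],
            min_visits=cfg.bursts.min_visits,
        )
        try:
            cond = bursts_mod.conditioned_intervals(
                [t.event_onsets for t in trains],
                [stc.gamma_full(T) for stc in stcs],
                fs,
                bad_masks=[fx.session.bad_mask for fx in fixtures],
                min_obs=cfg.bursts.min_obs,
            )
        except ValueError as exc:
            logger.warning("conditioned intervals undersampled: %s", exc)
            cond = None
        return grid, curves, shuffle, svf, cond

    grid, curves, shuffle, svf, cond = _stage("bursts")(bursts_stage)()
    fano_rows = []
    for i, c in enumerate(curves):
        for w, f in zip(grid, c.fano[0]):
            fano_rows.append({"subject": i, "train": "replay", "window_s": w, "fano": f})
    pd.DataFrame(fano_rows).to_csv(out / "fano_curves.tsv", sep="\t", index=False)
    obs = shuffle.observed
    summary["replay_fano_group"] = [None if not np.isfinite(x) else float(x) for x in obs]
    summary["fano_reject_any_ge_10s"] = bool(
        np.any(shuffle.reject[shuffle.window_lengths >= 10.0])
    )
    summary["state_visit_anova_max_p"] = (
        None if not np.isfinite(svf.anova_max_p) else float(svf.anova_max_p)
    )
    summary["conditioned_interval_anova_p"] = (
        None if cond is None or not np.isfinite(cond.anova_p) else float(cond.anova_p)
    )

    # --- invariant checks asserted on every run ---
    for stc in stcs:
        ok = np.isfinite(stc.gamma).all(axis=0)
        assert np.allclose(stc.gamma[:, ok].sum(axis=0), 1.0, atol=1e-6)
    for train in trains:
        vals = train.trace[np.isfinite(train.trace)]
        assert vals.min() >= 0.0 and vals.max() <= 1.0
    assert np.allclose(resp.values.sum(axis=0), 0.0, atol=1e-6)
    summary["invariants_ok"] = True

    summary["validation"] = validate_against_truth(fixtures, stcs, trains, model)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def validate_against_truth(
    fixtures: list[SubjectFixture],
    stcs: list[hmm.StateTimecourse],
    trains: list[replay.ReplayEventTrain],
    model: hmm.HmmModel,
    tol_samples: int = 2,
) -> dict:
    """Recovery metrics against planted ground truth."""
    T = fixtures[0].session.n_samples
    K_true = int(max(fx.truth.state_path.max() for fx in fixtures)) + 1
    K = max(model.K, K_true)
    accs, precs, recs = [], [], []
    for fx, stc, train in zip(fixtures, stcs, trains):
        accs.append(hmm.state_match_accuracy(fx.truth.state_path, stc.viterbi_full(T), K))
        p, r = match_event_trains(train.event_onsets, fx.truth.replay_times, tol_samples)
        precs.append(p)
        recs.append(r)
    return {
        "state_match_accuracy": float(np.mean(accs)),
        "replay_precision": float(np.mean(precs)),
        "replay_recall": float(np.mean(recs)),
    }
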