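"""End-to-end orchestration, file I/O and reproducibility plumbing.

A pipeline run takes two labeled conditions (synthetic or from files),
and for each analysis band computes: band-power tables, per-epoch PLV
matrices, surrogate-thresholded binary networks, WKPN/WDC/WPR importance
profiles, and SVM classification reports.  Every artifact embeds the
configuration hash and seeds, so a rerun with the same config reproduces
rankings and split assignments exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import yaml

from . import classify as clf
from . import connectivity as conn
from . import spectral, synth, wkpn
from .containers import MultichannelEpoch
from .montage import CHANNELS_62, canonical_order

__all__ = ["PipelineConfig", "run_pipeline", "read_recording",
           "save_epochs", "load_epochs"]

DEFAULT_BANDS = ("theta", "alpha", "beta")


@dataclasses.dataclass
class PipelineConfig:
    """Fully serializable description of one pipeline run."""

    channels: tuple[str, ...] = CHANNELS_62
    bands: tuple[str, ...] = DEFAULT_BANDS
    synth: dict | None = None          # {"easy": {...}, "hard": {...}}
    inputs: dict | None = None         # {"format": ..., "easy": [...], ...}
    n_surrogates: int = 200
    alpha: float = 0.05
    normalization: str = "sum"
    invert_weights: bool = False
    n_repetitions: int = 20
    test_size: float = 0.4
    feature_lengths: tuple[int, ...] | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["channels"] = list(d["channels"])
        d["bands"] = list(d["bands"])
        if d["feature_lengths"] is not None:
            d["feature_lengths"] = list(d["feature_lengths"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "channels" in d and d["channels"]:
            d["channels"] = tuple(d["channels"])
        if "bands" in d:
            d["bands"] = tuple(d["bands"])
        if d.get("feature_lengths"):
            d["feature_lengths"] = tuple(d["feature_lengths"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# signal I/O


def save_epochs(epochs: list[MultichannelEpoch], path: str | Path) -> None:
    """Write epochs to a plain array container (.npz) + JSON sidecar."""
    path = Path(path)
    data = np.stack([ep.data for ep in epochs])
    np.savez(path.with_suffix(".npz"), data=data)
    sidecar = {
        "rate": epochs[0].rate,
        "channels": list(epochs[0].channels),
        "labels": [ep.label for ep in epochs],
        "epoch_ids": [ep.epoch_id for ep in epochs],
        "meta": [ep.meta for ep in epochs],
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, default=str)


def load_epochs(path: str | Path) -> list[MultichannelEpoch]:
    """Inverse of :func:`save_epochs`."""
    path = Path(path)
    data = np.load(path.with_suffix(".npz"))["data"]
    with open(path.with_suffix(".json")) as fh:
        sc = json.load(fh)
    return [MultichannelEpoch(data=data[k], rate=sc["rate"],
                              channels=tuple(sc["channels"]),
                              label=sc["labels"][k],
                              epoch_id=sc["epoch_ids"][k],
                              meta=sc["meta"][k] or {})
            for k in range(data.shape[0])]


def read_recording(path: str | Path, format: str = "array",
                   expected_rate: float | None = None,
                   ) -> tuple[np.ndarray, float, tuple[str, ...]]:
    """Read a continuous multichannel recording.

    Supported formats: ``"array"`` (``.npz`` with a ``data`` array of
    shape samples x channels, plus a ``.json`` sidecar with ``channels``
    and ``rate``) and ``"edf"`` (requires :mod:`mne`).

    Channels are reordered to canonical montage order and the mastoid
    references M1/M2 dropped when present.  Unknown labels raise an
    error naming them; a rate different from ``expected_rate`` raises.
    """
    path = Path(path)
    if format == "array":
        data = np.load(path.with_suffix(".npz"))["data"]
        with open(path.with_suffix(".json")) as fh:
            sc = json.load(fh)
        labels, rate = list(sc["channels"]), float(sc["rate"])
    elif format == "edf":
        import mne
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data().T * 1e6  # volts -> microvolts
        labels, rate = list(raw.ch_names), float(raw.info["sfreq"])
    else:
        raise ValueError(f"unknown format {format!r}")
    if expected_rate is not None and rate != expected_rate:
        raise ValueError(f"rate {rate} Hz != expected {expected_rate} Hz")
    idx = canonical_order(labels)
    return data[:, idx], rate, tuple(labels[i].upper() for i in idx)


# ---------------------------------------------------------------------------
# orchestration


def _condition_from_config(name: str, cfg: dict,
                           channels: tuple[str, ...]) -> synth.ConditionSpec:
    specs = {}
    for band_name, osc in cfg["oscillators"].items():
        osc = dict(osc)
        osc.setdefault("channels", channels)
        osc["coupling_groups"] = tuple(
            tuple(g) for g in osc.get("coupling_groups", ()))
        specs[band_name] = synth.OscillatorSpec(**osc)
    return synth.ConditionSpec(label=name, oscillator_specs=specs,
                               n_epochs=cfg.get("n_epochs", 20),
                               seed=cfg.get("seed", 0))


def _gather_epochs(config: PipelineConfig) -> list[MultichannelEpoch]:
    if config.synth is not None:
        conditions = [_condition_from_config(name, c, config.channels)
                      for name, c in sorted(config.synth.items())]
        if len(conditions) != 2:
            raise ValueError("exactly two synth conditions required")
        return synth.generate_dataset(*conditions)
    if config.inputs is None:
        raise ValueError("config provides neither synth nor inputs")
    fmt = config.inputs.get("format", "array")
    epochs = []
    for label in ("easy", "hard"):
        for p in config.inputs.get(label, []):
            data, rate, chans = read_recording(p, format=fmt)
            segs = spectral.preprocess(data, rate, chans)
            for ep in segs:
                ep.label = label
                epochs.append(ep)
    return epochs


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full analysis for every configured band.

    Writes, under ``out_dir``: the config + hash, a structured JSON-lines
    log, per-condition band-power tables, and per band: the surrogate
    threshold, per-epoch PLV matrices (TSV), binary networks (edge
    lists), importance profiles (JSON) and classification reports (JSON).

    Returns a summary dict with the per-band, per-method mean accuracies
    and artifact paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash
    config.to_yaml(out / "config.yaml")
    log_path = out / "log.jsonl"

    def log(stage: str, **kw) -> None:
        with open(log_path, "a") as fh:
            fh.write(json.dumps({"t": time.time(), "stage": stage,
                                 "config_hash": cfg_hash, **kw}) + "\n")

    log("start", seed=config.seed, bands=list(config.bands))
    epochs = _gather_epochs(config)
    if not epochs:
        raise RuntimeError("stage gather: no epochs produced")
    labels = [ep.label for ep in epochs]
    log("gather", n_epochs=len(epochs),
        per_label={lab: labels.count(lab) for lab in sorted(set(labels))})

    # band-power tables per condition
    for lab in sorted(set(labels)):
        eps = [ep for ep in epochs if ep.label == lab]
        table = spectral.band_power_table(eps)
        table.to_csv(out / f"band_power_{lab}.tsv", sep="\t", index=False)
    log("band_power")

    summary: dict = {"config_hash": cfg_hash, "bands": {}}
    rng = np.random.default_rng(config.seed)
    for band_name in config.bands:
        band = spectral.BANDS[band_name]
        bdir = out / band_name
        for sub in ("plv", "networks", "profiles", "reports"):
            (bdir / sub).mkdir(parents=True, exist_ok=True)

        thr_seed = int(rng.integers(2**31))
        try:
            thr = conn.surrogate_threshold(
                epochs, band, n_surrogates=config.n_surrogates,
                alpha=config.alpha, seed=thr_seed)
        except Exception as err:
            raise RuntimeError(
                f"stage surrogate_threshold, band {band_name}: {err}"
            ) from err
        with open(bdir / "threshold.json", "w") as fh:
            json.dump({"config_hash": cfg_hash, "seed": thr_seed,
                       **dataclasses.asdict(thr)}, fh, indent=1)
        log("threshold", band=band_name, T=thr.threshold, seed=thr_seed)

        profiles, baselines = [], {"wdc": [], "wpr": []}
        for ep in epochs:
            tag = f"epoch_{ep.epoch_id:03d}_{ep.label}"
            try:
                plv = conn.plv_matrix(ep, band)
                net = conn.binarize(plv, thr)
                prof = wkpn.node_importance(
                    net, normalization=config.normalization,
                    invert_weights=config.invert_weights)
            except Exception as err:
                raise RuntimeError(
                    f"stage connectivity/ranking, band {band_name}, "
                    f"{tag}: {err}") from err
            profiles.append(prof)
            baselines["wdc"].append(wkpn.wdc(net))
            baselines["wpr"].append(wkpn.wpr(net))

            header = "\t".join(plv.node_labels)
            np.savetxt(bdir / "plv" / f"{tag}.tsv", plv.values,
                       delimiter="\t", header=header, comments="")
            with open(bdir / "networks" / f"{tag}.edges", "w") as fh:
                fh.write(f"# config_hash {cfg_hash}\n")
                for a, b in net.edge_list():
                    fh.write(f"{a}\t{b}\n")
            with open(bdir / "profiles" / f"{tag}.json", "w") as fh:
                json.dump({"config_hash": cfg_hash,
                           "node_labels": list(prof.node_labels),
                           "N": prof.N.tolist(), "H": prof.H.tolist(),
                           "c": prof.c.tolist(), "Q": prof.Q.tolist(),
                           "ranking": list(prof.ranking), "d": prof.d},
                          fh)
        log("networks", band=band_name, n=len(profiles))

        ds = {"wkpn": clf.build_features(profiles, labels, band=band_name)}
        node_labels = profiles[0].node_labels
        for name, vecs in baselines.items():
            ds[name] = clf.StateDataset(
                X=np.vstack(vecs), y=np.asarray(labels),
                node_labels=node_labels, band=band_name, method=name)
        eval_seed = int(rng.integers(2**31))
        reports = clf.compare_methods(ds, n_repetitions=config.n_repetitions,
                                      seed=eval_seed)
        band_summary = {}
        for name, rep in reports.items():
            band_summary[name] = rep.mean_accuracy
            with open(bdir / "reports" / f"{name}.json", "w") as fh:
                json.dump({"config_hash": cfg_hash, "seed": eval_seed,
                           "method": name, "band": band_name,
                           "split_ratio": rep.split_ratio,
                           "n_repetitions": rep.n_repetitions,
                           "accuracies": rep.accuracies.tolist(),
                           "mean_accuracy": rep.mean_accuracy}, fh,
                          indent=1)
        if config.feature_lengths:
            sweep = clf.length_sweep(ds["wkpn"],
                                     list(config.feature_lengths),
                                     n_repetitions=config.n_repetitions,
                                     seed=eval_seed)
            band_summary["length_sweep"] = sweep["curve"]
            band_summary["best_length"] = sweep["best_length"]
            with open(bdir / "reports" / "length_sweep.json", "w") as fh:
                json.dump({"config_hash": cfg_hash, "seed": eval_seed,
                           "curve": {str(k): v for k, v
                                     in sweep["curve"].items()},
                           "best_length": sweep["best_length"]}, fh,
                          indent=1)
        log("classify", band=band_name,
            **{k: v for k, v in band_summary.items()
               if isinstance(v, float)})
        summary["bands"][band_name] = band_summary

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=str)
    log("done")
    return summary
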