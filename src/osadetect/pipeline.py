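"""End-to-end experiment orchestration.

``run_experiment`` chains: synthetic data generation (or user-supplied
records) -> preprocessing -> three image encodings -> training the four
member classifiers -> soft-voting fusion -> metrics and artifacts.  One
global seed expands deterministically into per-stage seeds, so a run is a
pure function of its config.
"""

from __future__ import annotations

import hashlib
import json
import time
import sys
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import train_test_split

from . import cwt_encoder, gaf_encoder, models, train_eval
from .ecg_io import EcgRecord
from .ensemble import (MEMBER_KEYS, EnsembleWeights, MemberPredictions,
                       accuracy_weights, soft_vote)
from .errors import OsaDetectError, ValidationError
from .preprocess import PreprocessConfig, preprocess_record
from .rendering import DEFAULT_COLORMAP
from .synthetic_ecg import SynthParams, generate_dataset
from .train_eval import TrainConfig

MODALITIES = ("CWT", "GASF", "GADF")


@dataclass
class RunConfig:
    """Declarative description of a full experiment."""

    # synthetic data source (ignored when records are passed explicitly)
    n_records: int = 20
    minutes_per_record: int = 20
    apnea_fraction: float = 0.5
    synth: SynthParams = field(default_factory=SynthParams)
    # preprocessing / encoding
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    wavelet: cwt_encoder.WaveletParams = field(
        default_factory=cwt_encoder.WaveletParams)
    n_scales: int = 128
    paa_length: int = 224
    colormap: str = DEFAULT_COLORMAP
    # members and training
    members: tuple = MEMBER_KEYS
    train: TrainConfig = field(default_factory=lambda: TrainConfig(
        epochs=4, batch_size=16, learning_rate=3e-3, width_multiplier=0.125))
    test_fraction: float = 0.2
    val_fraction: float = 0.1
    weights: tuple | None = None     # None -> accuracy-proportional
    # bookkeeping
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if tuple(map(tuple, self.members)) != MEMBER_KEYS:
            raise ValidationError(
                f"the ensemble requires exactly the four members {MEMBER_KEYS}"
            )
        if not 0 < self.test_fraction < 1 or not 0 <= self.val_fraction < 1:
            raise ValidationError("invalid split fractions")


@dataclass
class ModalityDataset:
    """Aligned encoded images for one modality."""

    modality: str
    images: np.ndarray            # (n, 224, 224, 3) float32
    labels: np.ndarray            # (n,) int, 1 = A
    keys: list[tuple[str, int]]   # (record_id, minute_index)


@dataclass
class ExperimentResult:
    member_reports: dict
    ensemble_report: train_eval.MetricsReport
    weights: EnsembleWeights
    n_segments: int
    n_test: int
    artifacts: dict = field(default_factory=dict)

    def metrics_dict(self) -> dict:
        return {
            "members": {k: v.to_dict() for k, v in self.member_reports.items()},
            "ensemble": self.ensemble_report.to_dict(),
            "weights": self.weights.w.tolist(),
            "n_segments": self.n_segments,
            "n_test": self.n_test,
        }


def _log(msg: str) -> None:
    print(f"[osadetect] {msg}", file=sys.stderr, flush=True)


def build_hybrid_datasets(records: list[EcgRecord],
                          config: RunConfig) -> dict[str, ModalityDataset]:
    """Preprocess records and encode every kept segment in all 3 modalities.

    Degenerate (flat) segments are dropped from every modality, so the three
    datasets stay aligned on (record_id, minute_index).
    """
    if not records:
        raise ValidationError("need at least one labeled record")
    segments = []
    for rec in records:
        segments.extend(preprocess_record(rec, config.preprocess))
    kept = [s for s in segments if np.ptp(s.samples) > 0]
    if len(kept) < len(segments):
        warnings.warn(f"dropped {len(segments) - len(kept)} flat segment(s)",
                      RuntimeWarning, stacklevel=2)
    if not kept:
        raise ValidationError("no usable segments after preprocessing")

    fs = kept[0].fs
    scales = cwt_encoder.default_scales(fs, config.wavelet,
                                        n_scales=config.n_scales)
    bank = cwt_encoder.CwtBank(len(kept[0].samples), fs, scales, config.wavelet)
    out: dict[str, ModalityDataset] = {}
    images = {m: np.empty((len(kept), 224, 224, 3), dtype=np.float32)
              for m in MODALITIES}
    for i, seg in enumerate(kept):
        src = (seg.record_id, seg.minute_index)
        coeffs = bank.transform(seg.samples)
        img = cwt_encoder.render_scalogram(coeffs, colormap=config.colormap,
                                           source=src, label=seg.label)
        images["CWT"][i] = img.pixels
        for kind in ("GASF", "GADF"):
            img = gaf_encoder.encode_segment(
                seg.samples, kind, paa_length=config.paa_length,
                colormap=config.colormap, source=src, label=seg.label)
            images[kind][i] = img.pixels
    labels = np.array([1 if s.label == "A" else 0 for s in kept])
    keys = [(s.record_id, s.minute_index) for s in kept]
    for m in MODALITIES:
        out[m] = ModalityDataset(modality=m, images=images[m],
                                 labels=labels, keys=keys)
    return out


def _stage_seeds(seed: int, n_members: int) -> dict:
    ss = np.random.SeedSequence(seed)
    state = ss.generate_state(3 + n_members) % (2 ** 31 - 1)
    return {
        "data": int(state[0]),
        "split": int(state[1]),
        "val_split": int(state[2]),
        "members": [int(s) for s in state[3:]],
    }


def _member_classifier(arch: str, seed: int, width: float) -> models.Classifier:
    spec = (models.inception_spec() if arch == "osa-inception"
            else models.residual_spec())
    return models.instantiate(spec, seed, width_multiplier=width)


def run_experiment(config: RunConfig,
                   records: list[EcgRecord] | None = None) -> ExperimentResult:
    """Run the full pipeline and return (and optionally persist) the results."""
    t0 = time.time()
    seeds = _stage_seeds(config.seed, len(config.members))
    stage = "generate"
    try:
        if records is None:
            records = generate_dataset(config.n_records,
                                       config.minutes_per_record,
                                       config.apnea_fraction,
                                       seed=seeds["data"],
                                       params=config.synth)
            _log(f"generated {len(records)} synthetic records "
                 f"({time.time() - t0:.1f}s)")
        stage = "encode"
        datasets = build_hybrid_datasets(records, config)
        labels = datasets["CWT"].labels
        keys = datasets["CWT"].keys
        n = len(labels)
        _log(f"encoded {n} segments x {len(MODALITIES)} modalities "
             f"({time.time() - t0:.1f}s)")

        stage = "split"
        idx = np.arange(n)
        trainval_idx, test_idx = train_test_split(
            idx, test_size=config.test_fraction, random_state=seeds["split"],
            stratify=labels)
        if config.val_fraction > 0:
            rel_val = config.val_fraction / (1.0 - config.test_fraction)
            train_idx, val_idx = train_test_split(
                trainval_idx, test_size=rel_val,
                random_state=seeds["val_split"],
                stratify=labels[trainval_idx])
        else:
            train_idx, val_idx = trainval_idx, test_idx

        stage = "train"
        member_probs_test, member_probs_val = [], []
        member_reports = {}
        val_accs = []
        for (modality, arch), m_seed in zip(config.members, seeds["members"]):
            name = f"{modality}_{arch}"
            ds = datasets[modality]
            clf = _member_classifier(arch, m_seed, config.train.width_multiplier)
            cfg = TrainConfig(
                epochs=config.train.epochs, batch_size=config.train.batch_size,
                learning_rate=config.train.learning_rate, seed=m_seed,
                width_multiplier=config.train.width_multiplier)
            train_eval.train(clf, ds.images[train_idx], labels[train_idx], cfg)
            p_val = train_eval.predict_proba(clf, ds.images[val_idx])
            p_test = train_eval.predict_proba(clf, ds.images[test_idx])
            member_probs_val.append(p_val)
            member_probs_test.append(p_test)
            acc_val = float(np.mean(p_val.argmax(1) == labels[val_idx]))
            # floor at half a count so a chance-level member keeps a valid weight
            val_accs.append(max(acc_val, 0.5 / max(len(val_idx), 1)))
            member_reports[name] = train_eval.evaluate(
                labels[test_idx], p_test.argmax(1), scores=p_test[:, 1])
            _log(f"trained {name}: val acc {acc_val:.3f}, "
                 f"test acc {member_reports[name].accuracy:.3f} "
                 f"({time.time() - t0:.1f}s)")

        stage = "ensemble"
        weights = (EnsembleWeights(np.asarray(config.weights))
                   if config.weights is not None
                   else accuracy_weights(val_accs))
        preds = MemberPredictions(np.stack(member_probs_test))
        fused_labels, fused_scores = soft_vote(preds, weights)
        ensemble_report = train_eval.evaluate(labels[test_idx], fused_labels,
                                              scores=fused_scores)
        _log(f"ensemble: acc {ensemble_report.accuracy:.3f}, "
             f"auc {ensemble_report.auc:.3f} ({time.time() - t0:.1f}s)")

        result = ExperimentResult(
            member_reports=member_reports, ensemble_report=ensemble_report,
            weights=weights, n_segments=n, n_test=len(test_idx))

        stage = "write"
        if config.out_dir is not None:
            result.artifacts = _write_artifacts(
                Path(config.out_dir), config, seeds, result, keys, labels,
                test_idx, preds, fused_labels, fused_scores)
        return result
    except OsaDetectError:
        raise
    except Exception as exc:
        raise OsaDetectError(f"pipeline failed in stage '{stage}': {exc}") from exc


def _write_artifacts(out_dir: Path, config: RunConfig, seeds: dict,
                     result: ExperimentResult, keys, labels, test_idx,
                     preds: MemberPredictions, fused_labels, fused_scores) -> dict:
    out_dir.mkdir(parents=True, exist_ok=True)
    metrics_path = out_dir / "metrics.json"
    metrics_path.write_text(json.dumps(result.metrics_dict(), indent=2,
                                       sort_keys=True))

    pred_path = out_dir / "predictions.csv"
    member_names = [f"{m}_{a}" for m, a in config.members]
    with pred_path.open("w") as fh:
        cols = ["record_id", "minute_index", "label"] + \
            [f"{n}_pA" for n in member_names] + ["fused_pA", "fused_label"]
        fh.write(",".join(cols) + "\n")
        for row, seg_i in enumerate(test_idx):
            rid, minute = keys[seg_i]
            vals = [rid, str(minute), "A" if labels[seg_i] else "N"]
            vals += [repr(float(preds.probs[m, row, 1]))
                     for m in range(len(member_names))]
            vals += [repr(float(fused_scores[row])),
                     "A" if fused_labels[row] else "N"]
            fh.write(",".join(vals) + "\n")

    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(labels[test_idx], fused_scores)
    roc_path = out_dir / "roc_points.csv"
    with roc_path.open("w") as fh:
        fh.write("threshold,fpr,tpr\n")
        for t, f, s in zip(thr, fpr, tpr):
            fh.write(f"{repr(float(t))},{repr(float(f))},{repr(float(s))}\n")

    cfg_dict = asdict(config)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True, default=str).encode()).hexdigest()
    prov_path = out_dir / "provenance.json"
    prov_path.write_text(json.dumps({
        "config": cfg_dict, "config_sha256": cfg_hash, "stage_seeds": seeds,
        "versions": {"numpy": np.__version__,
                     "python": sys.version.split()[0]},
    }, indent=2, sort_keys=True, default=str))
    return {"metrics": str(metrics_path), "predictions": str(pred_path),
            "roc": str(roc_path), "provenance": str(prov_path)}
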