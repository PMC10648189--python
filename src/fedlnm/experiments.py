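"""End-to-end experiment drivers.

Two result families are produced:

* the diagnostic-accuracy table of the seven imaging groups (point metrics and
  all pairwise comparisons) recomputed from the packaged contingency counts,
  with a discrepancy report for cells whose published values disagree with
  their own published counts;
* seeded federated-learning runs on the synthetic planted-signal cohort —
  text-only and multimodal — with metrics on the internal test pool, the
  cross-client validation sets and an ovarian-cancer-like external preset,
  plus ROC and loss-curve exports.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import cohort as ch
from .estimators import FederatedFusionClassifier
from .exceptions import InputError
from .federated import client_arrays, cross_validate_clients
from .stats import (ContingencyTable, compare_auc_unpaired, compare_proportions,
                    compute_metrics, load_packaged_contingency, load_published_metrics,
                    roc_from_scores, round_half_up)

__all__ = ["ExperimentSpec", "ResultsBundle", "reproduce_table5",
           "run_fl_experiment", "export_curves", "build_clients",
           "COMPARISON_PAIRS", "DEFAULT_LEARNING_RATE"]

GROUPS = ("CT", "MRI", "PET/CT", "C-M", "C-P", "M-P", "C-M-P")

#: The twelve published pairwise comparisons, in table order.
COMPARISON_PAIRS = (
    ("CT", "MRI"), ("CT", "PET/CT"), ("MRI", "PET/CT"),
    ("C-M", "C-P"), ("C-M", "M-P"), ("C-M", "C-M-P"),
    ("C-P", "M-P"), ("C-P", "C-M-P"), ("M-P", "C-M-P"),
    ("CT", "C-P"), ("PET/CT", "C-P"), ("MRI", "M-P"),
)

PERCENT_METRICS = ("sensitivity", "specificity", "ppv", "npv", "accuracy")

#: Preset learning rate for the default federated experiments (momentum SGD).
DEFAULT_LEARNING_RATE = 0.02


# ---------------------------------------------------------------------------
# Imaging-table reproduction
# ---------------------------------------------------------------------------

def _decimals(printed: str) -> int:
    return len(printed.split(".")[1]) if "." in printed else 0


def reproduce_table5(counts_path=None) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Recompute the seven-group diagnostic table from 2x2 counts.

    Returns ``(metrics, comparisons, discrepancies)``:

    * ``metrics`` — one row per group: sensitivity/specificity/PPV/NPV/accuracy
      (percent), AUC and its normal-approximation CI;
    * ``comparisons`` — one row per (pair, metric): chi-squared p-values for
      the five proportions plus the unpaired AUC z-test;
    * ``discrepancies`` — cells whose published value disagrees with the value
      recomputed from the published counts at the published precision.
    """
    if counts_path is None:
        tables = load_packaged_contingency()
    else:
        df = pd.read_csv(counts_path)
        tables = {r.group: ContingencyTable(int(r.tp), int(r.fp), int(r.fn), int(r.tn))
                  for r in df.itertuples(index=False)}
    missing = [g for g in GROUPS if g not in tables]
    if missing:
        raise InputError(f"missing contingency groups: {missing}")

    metrics = {g: compute_metrics(tables[g]) for g in GROUPS}
    rows = []
    for g in GROUPS:
        m = metrics[g]
        rows.append({
            "group": g,
            **{k: 100.0 * getattr(m, k) for k in PERCENT_METRICS},
            "auc": m.auc, "auc_ci_low": m.auc_ci[0], "auc_ci_high": m.auc_ci[1],
            "n": m.n,
        })
    metrics_df = pd.DataFrame(rows)

    comp_rows = []
    for g1, g2 in COMPARISON_PAIRS:
        t1, t2 = tables[g1], tables[g2]
        numerators = {
            "sensitivity": (t1.tp, t1.n_positive, t2.tp, t2.n_positive),
            "specificity": (t1.tn, t1.n_negative, t2.tn, t2.n_negative),
            "ppv": (t1.tp, t1.tp + t1.fp, t2.tp, t2.tp + t2.fp),
            "npv": (t1.tn, t1.tn + t1.fn, t2.tn, t2.tn + t2.fn),
            "accuracy": (t1.tp + t1.tn, t1.total, t2.tp + t2.tn, t2.total),
        }
        for name, (x1, n1, x2, n2) in numerators.items():
            c = compare_proportions(x1, n1, x2, n2, metric_name=name)
            comp_rows.append({"group1": g1, "group2": g2, "metric": name,
                              "method": c.method, "statistic": c.statistic,
                              "p_value": c.p_value, "significant": c.significant})
        c = compare_auc_unpaired(metrics[g1], t1, metrics[g2], t2)
        comp_rows.append({"group1": g1, "group2": g2, "metric": "auc",
                          "method": c.method, "statistic": c.statistic,
                          "p_value": c.p_value, "significant": c.significant})
    comparisons_df = pd.DataFrame(comp_rows)

    published = load_published_metrics().set_index("group")
    discrepancies = []
    for g in GROUPS:
        m = metrics[g]
        for name in PERCENT_METRICS:
            printed = published.loc[g, name]
            computed = round_half_up(100.0 * getattr(m, name), _decimals(printed))
            if computed != float(printed):
                discrepancies.append({"group": g, "metric": name,
                                      "published": float(printed), "computed": computed})
        printed_auc = published.loc[g, "auc"]
        computed_auc = round_half_up(m.auc, _decimals(printed_auc))
        if computed_auc != float(printed_auc):
            discrepancies.append({"group": g, "metric": "auc",
                                  "published": float(printed_auc), "computed": computed_auc})
    return metrics_df, comparisons_df, discrepancies


# ---------------------------------------------------------------------------
# Federated experiments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentSpec:
    """One federated experiment family: mode, preset, seeds and budget."""

    name: str = "default"
    mode: str = "multimodal"          # or "text_only"
    cohort_preset: str = "internal"   # cohort used for training
    seeds: tuple[int, ...] = (0, 1, 2)
    n_rounds: int = 20
    learning_rate: float = DEFAULT_LEARNING_RATE
    batch_size: int = 16
    local_epochs: int = 1
    image_size: int = 64
    include_external: bool = True

    def __post_init__(self) -> None:
        if not self.seeds:
            raise InputError("need at least one seed")
        if self.cohort_preset not in ("internal", "external_oc_like"):
            raise InputError(f"unknown cohort preset {self.cohort_preset!r}")


@dataclass
class ResultsBundle:
    """Per-seed metrics plus curve data for one experiment."""

    spec: ExperimentSpec
    per_seed: dict[int, dict[str, dict[str, float | None]]] = field(default_factory=dict)
    roc: dict[str, tuple[list[tuple[float, float]], float]] = field(default_factory=dict)
    loss_rows: list[dict] = field(default_factory=list)   # round, client, loss

    def summary(self) -> dict[str, dict[str, tuple[float, float]]]:
        """mean +- sd of each metric over seeds, per evaluation set."""
        out: dict[str, dict[str, tuple[float, float]]] = {}
        sets = next(iter(self.per_seed.values())).keys()
        for s in sets:
            out[s] = {}
            metrics = next(iter(self.per_seed.values()))[s].keys()
            for m in metrics:
                vals = [self.per_seed[seed][s][m] for seed in self.per_seed
                        if self.per_seed[seed][s][m] is not None]
                if vals:
                    sd = statistics.stdev(vals) if len(vals) > 1 else 0.0
                    out[s][m] = (statistics.mean(vals), sd)
        return out

    def mean_auc(self, set_name: str = "test") -> float:
        return self.summary()[set_name]["auc"][0]


def build_clients(seed: int, multimodal: bool, image_size: int = 64
                  ) -> tuple[ch.ClientDataset, ch.ClientDataset]:
    """Internal-preset cohort -> two clients with splits (and phantoms)."""
    recs = ch.generate_cohort(ch.federated_config(seed=seed))
    c0, c1 = ch.partition_clients(recs, seed=seed)
    out = []
    for c in (c0, c1):
        if multimodal:
            newrecs, images = ch.generate_images(
                c.records, ch.ImageConfig(height=image_size, width=image_size, seed=seed))
            c = ch.ClientDataset(c.client_id, newrecs, images)
        out.append(ch.split_train_test(c, 0.8, seed=seed))
    return out[0], out[1]


def _external_client(seed: int, multimodal: bool, image_size: int) -> ch.ClientDataset:
    cfg = ch.external_oc_config(seed=seed + 101)
    recs = ch.generate_cohort(cfg)
    images: dict[str, ch.SyntheticImage] = {}
    if multimodal:
        # externally acquired scans: same phantom family, degraded contrast
        img_cfg = ch.ImageConfig(height=image_size, width=image_size,
                                 contrast=0.245, seed=seed + 101)
        recs, images = ch.generate_images(recs, img_cfg)
    client = ch.ClientDataset(client_id=0, records=recs, images=images)
    return ch.split_train_test(client, 0.8, seed=seed + 101)


def _metrics_from_scores(scores: np.ndarray, y: np.ndarray) -> dict[str, float | None]:
    from .stats import build_contingency
    m = compute_metrics(build_contingency(scores >= 0.5, y))
    _, auc = roc_from_scores(scores, y)
    return {"sensitivity": m.sensitivity, "specificity": m.specificity,
            "accuracy": m.accuracy, "auc": auc, "n": float(len(y))}


def run_fl_experiment(spec: ExperimentSpec) -> ResultsBundle:
    """Run the federated pipeline once per seed and collect metrics and curves."""
    bundle = ResultsBundle(spec=spec)
    multimodal = spec.mode == "multimodal"
    for si, seed in enumerate(spec.seeds):
        clients = build_clients(seed, multimodal, spec.image_size)
        est = FederatedFusionClassifier(
            n_rounds=spec.n_rounds, local_epochs=spec.local_epochs,
            batch_size=spec.batch_size, learning_rate=spec.learning_rate,
            mode=spec.mode, image_size=spec.image_size, random_state=seed)
        est.fit_clients(list(clients))

        sets: dict[str, dict[str, float | None]] = {}
        pooled: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for split in ("train", "test"):
            scores, ys = [], []
            for c in clients:
                data = client_arrays(c, split, spec.mode)
                p = est.model_.predict_proba(data["X"], data["images"])
                scores.append(p[:, 1])
                ys.append(data["y"])
            sc, yy = np.concatenate(scores), np.concatenate(ys)
            sets[split] = _metrics_from_scores(sc, yy)
            pooled[split] = (sc, yy)
        cv = cross_validate_clients(clients, est.global_params_, est.config_)
        sc = np.concatenate([cv["client0"]["scores"], cv["client1"]["scores"]])
        yy = np.concatenate([cv["client0"]["labels"], cv["client1"]["labels"]])
        sets["validation"] = _metrics_from_scores(sc, yy)
        pooled["validation"] = (sc, yy)
        if spec.include_external:
            ext = _external_client(seed, multimodal, spec.image_size)
            data = client_arrays(ext, "all", spec.mode)
            p = est.model_.predict_proba(data["X"], data["images"])
            sets["external"] = _metrics_from_scores(p[:, 1], data["y"])
            pooled["external"] = (p[:, 1], data["y"])
        bundle.per_seed[seed] = sets

        if si == 0:
            for name, (sc, yy) in pooled.items():
                if name == "train":
                    continue
                points, auc = roc_from_scores(sc, yy)
                bundle.roc[name] = (points, auc)
            for log in est.round_logs_:
                for cid, losses in log.client_losses.items():
                    bundle.loss_rows.append({
                        "round": log.round_index, "client": cid,
                        "loss": float(np.mean(losses))})
    return bundle


def save_bundle(bundle: ResultsBundle, path) -> None:
    """Persist a ResultsBundle as JSON (for later curve export)."""
    import dataclasses
    import json
    payload = {
        "spec": dataclasses.asdict(bundle.spec),
        "per_seed": {str(k): v for k, v in bundle.per_seed.items()},
        "roc": {k: {"points": v[0], "auc": v[1]} for k, v in bundle.roc.items()},
        "loss_rows": bundle.loss_rows,
    }
    Path(path).write_text(json.dumps(payload))


def load_bundle(path) -> ResultsBundle:
    import json
    payload = json.loads(Path(path).read_text())
    spec_d = payload["spec"]
    spec_d["seeds"] = tuple(spec_d["seeds"])
    bundle = ResultsBundle(spec=ExperimentSpec(**spec_d))
    bundle.per_seed = {int(k): v for k, v in payload["per_seed"].items()}
    bundle.roc = {k: ([tuple(p) for p in v["points"]], v["auc"])
                  for k, v in payload["roc"].items()}
    bundle.loss_rows = payload["loss_rows"]
    return bundle


def export_curves(bundle: ResultsBundle, outdir) -> list[Path]:
    """Write metric, ROC and loss CSVs plus rendered PNG plots; returns paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputError(f"cannot create output directory {outdir}: {exc}") from exc
    written: list[Path] = []

    def _fmt(x) -> str:
        return repr(float(x))

    rows = []
    for seed, sets in bundle.per_seed.items():
        for sname, metrics in sets.items():
            rows.append({"seed": seed, "set": sname,
                         **{k: v for k, v in metrics.items()}})
    p = outdir / "metrics_by_seed.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    written.append(p)

    srows = []
    for sname, metrics in bundle.summary().items():
        for m, (mean, sd) in metrics.items():
            srows.append({"set": sname, "metric": m, "mean": mean, "sd": sd})
    p = outdir / "summary.csv"
    pd.DataFrame(srows).to_csv(p, index=False)
    written.append(p)

    for sname, (points, auc) in bundle.roc.items():
        p = outdir / f"roc_{sname}.csv"
        with open(p, "w") as fh:
            fh.write("fpr,tpr\n")
            for fpr, tpr in points:
                fh.write(f"{_fmt(fpr)},{_fmt(tpr)}\n")
        written.append(p)

    p = outdir / "loss.csv"
    with open(p, "w") as fh:
        fh.write("round,client,loss\n")
        for row in bundle.loss_rows:
            fh.write(f"{row['round']},{row['client']},{_fmt(row['loss'])}\n")
    written.append(p)

    if bundle.roc:
        fig, ax = plt.subplots(figsize=(5, 5))
        for sname, (points, auc) in bundle.roc.items():
            xs, ys = zip(*points)
            ax.plot(xs, ys, label=f"{sname} (AUC {auc:.3f})")
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend()
        fig.savefig(outdir / "roc.png", dpi=120)
        plt.close(fig)
        written.append(outdir / "roc.png")
    if bundle.loss_rows:
        fig, ax = plt.subplots(figsize=(6, 4))
        df = pd.DataFrame(bundle.loss_rows)
        for cid, grp in df.groupby("client"):
            ax.plot(grp["round"], grp["loss"], label=f"client {cid}")
        ax.set_xlabel("federated round")
        ax.set_ylabel("mean training loss")
        ax.legend()
        fig.savefig(outdir / "loss.png", dpi=120)
        plt.close(fig)
        written.append(outdir / "loss.png")
    return written
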