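"""Channel-level evaluation: ROC/AUC, leave-one-patient-out CV, band
ablation, and baseline classifiers (real-valued CNN, SVM, random forest).

A classifier labels individual windows; a channel's score is the fraction
of its windows predicted pathological; channels are then classified by
thresholding that fraction, and the threshold sweep yields the ROC curve.
The operating point reported is the Youden-optimal threshold (maximising
sensitivity + specificity - 1).

Cross-validation is leave-one-patient-out: train on all windows of all but
one patient, test on the held-out patient's windows, rotate, and average
the per-patient AUCs unweighted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.svm import SVC

from . import core, cvcnn
from .core import BandMask, CVPACImage
from .io import PATHOLOGICAL

__all__ = [
    "ChannelScore",
    "ROCResult",
    "CVPACDataset",
    "channel_scores",
    "roc_auc",
    "plot_roc",
    "loocv",
    "LOOCVResult",
    "run_ablation_experiment",
    "baseline",
    "CVCNNClassifier",
    "RealCNNClassifier",
    "SVMClassifier",
    "RFClassifier",
    "svm_grid_search",
    "SVM_C_GRID",
    "SVM_GAMMA_GRID",
]

#: Grid-search ranges for the SVM baseline: C stepping by 2^4 from 2^2
#: (so 2^2 ... 2^18, covering the default optimum) and gamma in
#: 2^-10, 2^-8, ..., 2^10.
SVM_C_GRID = [2.0**e for e in range(2, 21, 4)]
SVM_GAMMA_GRID = [2.0**e for e in range(-10, 11, 2)]


@dataclass(frozen=True)
class ChannelScore:
    channel_label: str
    patient: str
    pathological_fraction: float
    truth: bool
    n_windows: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pathological_fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    optimal_threshold: float
    sensitivity_at_optimal: float
    specificity_at_optimal: float


@dataclass
class CVPACDataset:
    """Labelled comodulograms with their channel/patient provenance."""

    images: list[CVPACImage]

    def __post_init__(self) -> None:
        for im in self.images:
            if im.label is None:
                raise ValueError("dataset images must be labelled")
            if "channel" not in im.provenance:
                raise ValueError("dataset images must record their channel")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def labels(self) -> list[str]:
        return [im.label for im in self.images]

    @property
    def channels(self) -> list[str]:
        return [im.provenance["channel"] for im in self.images]

    @property
    def patients(self) -> list[str]:
        return [im.provenance.get("patient", "") for im in self.images]

    def patient_set(self) -> list[str]:
        return sorted(set(self.patients))

    def split_by_patient(self, patient: str) -> tuple["CVPACDataset", "CVPACDataset"]:
        train = [im for im in self.images if im.provenance.get("patient") != patient]
        test = [im for im in self.images if im.provenance.get("patient") == patient]
        return CVPACDataset(train), CVPACDataset(test)

    def transformed(self, fn) -> "CVPACDataset":
        return CVPACDataset([fn(im) for im in self.images])


def channel_scores(
    dataset: CVPACDataset,
    probabilities: np.ndarray,
    decision_rule: str = "argmax",
    prob_threshold: float = 0.5,
) -> list[ChannelScore]:
    """Aggregate per-window predictions into per-channel pathological
    fractions.

    ``probabilities`` has shape (n_windows, 2) with column 1 the
    pathological probability.  ``decision_rule="argmax"`` counts a window
    as pathological when that class wins; ``"prob_threshold"`` compares the
    probability against ``prob_threshold``.
    """
    probabilities = np.asarray(probabilities, float)
    if probabilities.shape[0] != len(dataset):
        raise ValueError("one probability row per window required")
    if decision_rule == "argmax":
        pred = probabilities[:, 1] >= probabilities[:, 0]
    elif decision_rule == "prob_threshold":
        pred = probabilities[:, 1] >= prob_threshold
    else:
        raise ValueError(f"unknown decision rule {decision_rule!r}")
    frac: dict[tuple[str, str], list] = {}
    truth: dict[tuple[str, str], bool] = {}
    for im, p in zip(dataset.images, pred):
        key = (im.provenance.get("patient", ""), im.provenance["channel"])
        frac.setdefault(key, []).append(bool(p))
        truth[key] = im.label == PATHOLOGICAL
    return [
        ChannelScore(
            channel_label=chan,
            patient=pat,
            pathological_fraction=float(np.mean(votes)),
            truth=truth[(pat, chan)],
            n_windows=len(votes),
        )
        for (pat, chan), votes in sorted(frac.items())
    ]


def roc_auc(scores: Sequence[ChannelScore]) -> ROCResult:
    """ROC over channel fractions with trapezoidal AUC and Youden point.

    Ties in the Youden statistic are broken toward the lower threshold.
    """
    truths = np.array([s.truth for s in scores], bool)
    fracs = np.array([s.pathological_fraction for s in scores], float)
    if truths.all() or not truths.any():
        raise ValueError("both truth classes must be present")
    fpr, tpr, thresholds = roc_curve(truths, fracs)
    auc = float(np.trapezoid(tpr, fpr))
    youden = tpr - fpr
    best = np.flatnonzero(youden == youden.max())[-1]  # thresholds descend
    return ROCResult(
        thresholds=thresholds,
        sensitivity=tpr,
        specificity=1 - fpr,
        auc=auc,
        optimal_threshold=float(min(thresholds[best], 1.0)),
        sensitivity_at_optimal=float(tpr[best]),
        specificity_at_optimal=float(1 - fpr[best]),
    )


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------


class CVCNNClassifier:
    """Complex-valued CNN on complex comodulograms."""

    def __init__(self, config: cvcnn.CVCNNConfig | None = None) -> None:
        self.config = config or cvcnn.CVCNNConfig.small()
        self.model: cvcnn.TrainedModel | None = None

    def fit(self, dataset: CVPACDataset) -> "CVCNNClassifier":
        self.model = cvcnn.train(dataset.images, config=self.config)
        return self

    def predict_proba(self, dataset: CVPACDataset) -> np.ndarray:
        return cvcnn.predict(self.model, dataset.images)


class RealCNNClassifier:
    """Real-valued CNN on two-layer (real/imag) or strength-only images."""

    def __init__(
        self,
        representation: str = "two_layer",
        config: cvcnn.CVCNNConfig | None = None,
    ) -> None:
        self.representation = representation
        in_channels = 2 if representation == "two_layer" else 1
        base = config or cvcnn.CVCNNConfig.small()
        from dataclasses import replace

        self.config = replace(
            base, complex_weights=False, in_channels=in_channels, readout="real"
        )
        self.model: cvcnn.TrainedModel | None = None

    def _x(self, dataset: CVPACDataset) -> np.ndarray:
        return cvcnn.to_two_layer_real(dataset.images, mode=self.representation)

    def fit(self, dataset: CVPACDataset) -> "RealCNNClassifier":
        self.model = cvcnn.train(
            self._x(dataset), labels=dataset.labels, config=self.config
        )
        return self

    def predict_proba(self, dataset: CVPACDataset) -> np.ndarray:
        return cvcnn.predict(self.model, self._x(dataset))


def _flat_features(dataset: CVPACDataset, representation: str) -> np.ndarray:
    x = cvcnn.to_two_layer_real(dataset.images, mode=representation)
    return x.reshape(x.shape[0], -1)


def _encode(labels: list[str]) -> np.ndarray:
    return np.array([lab == PATHOLOGICAL for lab in labels], int)


class SVMClassifier:
    """RBF-kernel SVM on flattened per-part pixel features.

    Defaults to C = 2^18, gamma = 2^2; ``svm_grid_search`` explores the
    printed C/gamma grids on a validation split.
    """

    def __init__(
        self,
        representation: str = "two_layer",
        C: float = 2.0**18,
        gamma: float = 2.0**2,
    ) -> None:
        self.representation = representation
        self.clf = SVC(C=C, gamma=gamma, kernel="rbf")

    def fit(self, dataset: CVPACDataset) -> "SVMClassifier":
        self.clf.fit(_flat_features(dataset, self.representation), _encode(dataset.labels))
        return self

    def predict_proba(self, dataset: CVPACDataset) -> np.ndarray:
        d = self.clf.decision_function(_flat_features(dataset, self.representation))
        p = 1.0 / (1.0 + np.exp(-d))
        return np.column_stack([1 - p, p])


def svm_grid_search(
    train: CVPACDataset,
    validation: CVPACDataset,
    representation: str = "two_layer",
    C_grid: Sequence[float] = tuple(SVM_C_GRID),
    gamma_grid: Sequence[float] = tuple(SVM_GAMMA_GRID),
) -> tuple[float, float, float]:
    """Return (C, gamma, validation AUC) maximising channel-level AUC."""
    best = (None, None, -np.inf)
    for C in C_grid:
        for gamma in gamma_grid:
            clf = SVMClassifier(representation, C=C, gamma=gamma).fit(train)
            try:
                auc = roc_auc(channel_scores(validation, clf.predict_proba(validation))).auc
            except ValueError:
                continue
            if auc > best[2]:
                best = (C, gamma, auc)
    if best[0] is None:
        raise ValueError("no grid point could be evaluated")
    return best


class RFClassifier:
    """Random forest (100 trees) on flattened per-part pixel features."""

    def __init__(
        self,
        representation: str = "two_layer",
        n_trees: int = 100,
        seed: int = 0,
    ) -> None:
        self.representation = representation
        self.clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)

    def fit(self, dataset: CVPACDataset) -> "RFClassifier":
        self.clf.fit(_flat_features(dataset, self.representation), _encode(dataset.labels))
        return self

    def predict_proba(self, dataset: CVPACDataset) -> np.ndarray:
        return self.clf.predict_proba(_flat_features(dataset, self.representation))


# ---------------------------------------------------------------------------
# cross-validation and experiments
# ---------------------------------------------------------------------------


@dataclass
class LOOCVResult:
    per_patient: dict[str, ROCResult | None]
    mean_auc: float
    excluded: list[str] = field(default_factory=list)

    def report(self) -> pd.DataFrame:
        rows = []
        for patient, roc in self.per_patient.items():
            rows.append(
                {
                    "patient": patient,
                    "auc": roc.auc if roc else np.nan,
                    "sensitivity": roc.sensitivity_at_optimal if roc else np.nan,
                    "specificity": roc.specificity_at_optimal if roc else np.nan,
                    "optimal_threshold": roc.optimal_threshold if roc else np.nan,
                }
            )
        rows.append(
            {
                "patient": "Average",
                "auc": self.mean_auc,
                "sensitivity": np.nan,
                "specificity": np.nan,
                "optimal_threshold": np.nan,
            }
        )
        return pd.DataFrame(rows)


def plot_roc(results: dict[str, ROCResult | None], path) -> None:
    """Write a ROC-curve figure (one trace per patient) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, roc in results.items():
        if roc is None:
            continue
        ax.plot(1 - roc.specificity, roc.sensitivity, label=f"{name} ({roc.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def loocv(
    dataset: CVPACDataset,
    make_classifier: Callable[[int], object],
    seed: int = 0,
    ablate: str | None = None,
    restrict: str | None = None,
    decision_rule: str = "argmax",
) -> LOOCVResult:
    """Leave-one-patient-out cross-validation.

    ``make_classifier(round_seed)`` builds a fresh classifier per round.
    With ``ablate``, the named band is replaced by moment-matched noise —
    replacement statistics computed on the training split only, then
    applied to both splits.  With ``restrict`` ("gamma" or "hfo"), images
    are cut down to those high-frequency rows first.  Patients whose
    channels are single-class are excluded from the average with a warning.
    """
    patients = dataset.patient_set()
    if len(patients) < 2:
        raise ValueError("leave-one-patient-out needs >= 2 patients")
    seeds = np.random.SeedSequence(seed).spawn(len(patients))
    per_patient: dict[str, ROCResult | None] = {}
    excluded: list[str] = []
    for ss, patient in zip(seeds, patients):
        train_ds, test_ds = dataset.split_by_patient(patient)
        rng = np.random.default_rng(ss)
        if restrict is not None:
            mask = core.band_mask(train_ds.images[0].grid, restrict)
            train_ds = train_ds.transformed(lambda im: core.restrict_rows(im, mask))
            test_ds = test_ds.transformed(
                lambda im: core.restrict_rows(im, core.band_mask(im.grid, restrict))
            )
        if ablate is not None:
            mask = core.band_mask(train_ds.images[0].grid, ablate)
            stats = core.ablation_statistics(train_ds.images, mask)
            fn = lambda im: core.ablate_band(im, mask, seed=rng, stats=stats)
            train_ds = train_ds.transformed(fn)
            test_ds = test_ds.transformed(fn)
        round_seed = int(rng.integers(2**31 - 1))
        clf = make_classifier(round_seed)
        clf.fit(train_ds)
        scores = channel_scores(
            test_ds, clf.predict_proba(test_ds), decision_rule=decision_rule
        )
        try:
            per_patient[patient] = roc_auc(scores)
        except ValueError:
            warnings.warn(
                f"patient {patient}: single-class channels, excluded from AUC"
            )
            per_patient[patient] = None
            excluded.append(patient)
    aucs = [r.auc for r in per_patient.values() if r is not None]
    if not aucs:
        raise ValueError("no patient produced a valid ROC")
    return LOOCVResult(per_patient, float(np.mean(aucs)), excluded)


def run_ablation_experiment(
    dataset: CVPACDataset,
    band_name: str,
    make_classifier: Callable[[int], object],
    seed: int = 0,
) -> dict[str, float]:
    """Full LOOCV with one band replaced by noise, against the unablated run."""
    base = loocv(dataset, make_classifier, seed=seed)
    ablated = loocv(dataset, make_classifier, seed=seed, ablate=band_name)
    return {
        "band": band_name,
        "auc_unablated": base.mean_auc,
        "auc_ablated": ablated.mean_auc,
        "auc_drop": base.mean_auc - ablated.mean_auc,
    }


def baseline(
    kind: str,
    representation: str,
    dataset: CVPACDataset,
    seed: int = 0,
    config: cvcnn.CVCNNConfig | None = None,
) -> LOOCVResult:
    """LOOCV with one of the comparison classifiers.

    ``kind``: "real_cnn" (2-channel or strength-only images), "svm"
    (fixed C = 2^18, gamma = 2^2), or "rf" (100 trees); features for
    svm/rf are the flattened per-part pixel values.
    """
    from dataclasses import replace

    if kind == "real_cnn":
        base_cfg = config or cvcnn.CVCNNConfig.small()
        make = lambda s: RealCNNClassifier(representation, replace(base_cfg, seed=s))
    elif kind == "svm":
        make = lambda s: SVMClassifier(representation)
    elif kind == "rf":
        make = lambda s: RFClassifier(representation, seed=s)
    else:
        raise ValueError(f"unknown baseline kind {kind!r}")
    return loocv(dataset, make, seed=seed)
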