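"""Late decision fusion of odour and image predictions.

Two strategies operate at the prediction level. Max-confidence fusion takes
the label of whichever modality is more confident, falling back to the odour
prediction when the image is unavailable (the odour sensor works at night;
the camera does not) and on exact ties. Majority voting pools three or more
voters, drops unavailable ones, and breaks even splits by the most confident
voter; with fewer than three remaining voters it degrades to max-confidence.

The agreement analysis selects samples where the image modality produced a
prediction *and* both modalities output the same label; the accuracy inside
that subset is typically far above either modality alone (when their error
processes are roughly independent, both being wrong the same way is rare),
which makes agreed samples a natural source of high-confidence pseudolabels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .core import Prediction
from .classification import MetricsReport, compute_metrics
from .vision import project_accuracy

__all__ = [
    "FUSION_STRATEGIES",
    "AgreementResult",
    "FusionResult",
    "fuse_max_confidence",
    "fuse_majority",
    "agreement_analysis",
    "fusion_report",
]

FUSION_STRATEGIES = ("max_confidence", "majority")


def fuse_max_confidence(odour: Prediction, image: Prediction) -> Prediction:
    """Label of the higher-confidence modality; odour wins ties and nights."""
    if not odour.available and not image.available:
        raise ValueError("both modalities unavailable; nothing to fuse")
    if not image.available:
        src = odour
    elif not odour.available:
        src = image
    else:
        src = image if image.confidence > odour.confidence else odour
    return Prediction(
        sample_id=odour.sample_id or image.sample_id,
        label=src.label,
        confidence=src.confidence,
        modality="fused",
    )


def fuse_majority(predictions: Sequence[Prediction]) -> Prediction:
    """Majority label over available voters.

    Unavailable voters are dropped first. With fewer than three voters left
    the vote degenerates and max-confidence over the remainder decides; an
    even split is broken by the single most confident voter.
    """
    if not predictions:
        raise ValueError("no voters")
    voters = [p for p in predictions if p.available]
    if not voters:
        raise ValueError("no available voters")
    sid = predictions[0].sample_id

    def _winner(cands: Sequence[Prediction]) -> Prediction:
        return max(cands, key=lambda p: p.confidence)

    if len(voters) < 3:
        src = _winner(voters)
        return Prediction(sid, src.label, src.confidence, "fused")

    counts: dict[str, list[Prediction]] = {}
    for p in voters:
        counts.setdefault(p.label, []).append(p)
    best = max(len(v) for v in counts.values())
    leaders = [lbl for lbl, v in counts.items() if len(v) == best]
    if len(leaders) == 1:
        label = leaders[0]
        conf = max(p.confidence for p in counts[label])
    else:  # even split: most confident voter decides
        src = _winner([p for lbl in leaders for p in counts[lbl]])
        label, conf = src.label, src.confidence
    return Prediction(sid, label, conf, "fused")


@dataclass
class AgreementResult:
    """Modal-agreement subset statistics."""

    n_agreed: int
    n_total: int
    fraction_agreed: float
    accuracy_on_agreed: float
    agreed_sample_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_agreed": self.n_agreed,
            "n_total": self.n_total,
            "fraction_agreed": self.fraction_agreed,
            "accuracy_on_agreed": self.accuracy_on_agreed,
        }


def agreement_analysis(
    odour: Sequence[Prediction],
    image: Sequence[Prediction],
    labels: Sequence[str],
) -> AgreementResult:
    """Count samples where both modalities agree and score that subset.

    Agreement requires the image modality to have produced a prediction
    (available) and the two labels to match. Accuracy is computed only over
    the agreed subset; with no agreed samples it is reported as 0.
    """
    if not (len(odour) == len(image) == len(labels)):
        raise ValueError("modalities and labels must align")
    agreed_ids: list[str] = []
    correct = 0
    for o, im, t in zip(odour, image, labels):
        if o.sample_id != im.sample_id:
            raise ValueError(
                f"misaligned ids: {o.sample_id!r} vs {im.sample_id!r}"
            )
        if im.available and o.available and o.label == im.label:
            agreed_ids.append(o.sample_id)
            if o.label == str(t):
                correct += 1
    n = len(labels)
    n_agreed = len(agreed_ids)
    return AgreementResult(
        n_agreed=n_agreed,
        n_total=n,
        fraction_agreed=n_agreed / n if n else 0.0,
        accuracy_on_agreed=correct / n_agreed if n_agreed else 0.0,
        agreed_sample_ids=agreed_ids,
    )


@dataclass
class FusionResult:
    """Per-strategy fused metrics next to the unimodal baselines."""

    fused: dict[str, MetricsReport]
    fused_labels: dict[str, list[Prediction]]
    baselines: dict[str, float]
    deltas: dict[str, float]
    agreement: AgreementResult

    def to_dict(self) -> dict:
        return {
            "fused": {k: m.to_dict() for k, m in self.fused.items()},
            "baselines": self.baselines,
            "deltas": self.deltas,
            "agreement": self.agreement.to_dict(),
        }


def fusion_report(
    strategies: Sequence[str],
    odour: Sequence[Prediction],
    image: Sequence[Prediction],
    labels: Sequence[str],
    extra_voters: Sequence[Sequence[Prediction]] = (),
) -> FusionResult:
    """Evaluate the requested fusion strategies against unimodal baselines.

    Baselines: odour accuracy over all samples, image accuracy over available
    samples, and image accuracy projected to all samples with missing images
    counted wrong. Deltas are fused accuracy minus the best unimodal
    all-sample accuracy. ``extra_voters`` supplies additional odour models
    for majority voting (total voters = 2 + len(extra_voters)).
    """
    if not strategies:
        raise ValueError("need at least one fusion strategy")
    for s in strategies:
        if s not in FUSION_STRATEGIES:
            raise ValueError(f"unknown strategy {s!r}; known: {FUSION_STRATEGIES}")
    labels = [str(t) for t in labels]
    baselines = {
        "odour": project_accuracy(odour, labels, "all_counting_missing_wrong"),
        "image_available_only": project_accuracy(image, labels, "available_only"),
        "image_all": project_accuracy(image, labels, "all_counting_missing_wrong"),
    }
    best_unimodal = max(baselines["odour"], baselines["image_all"])

    fused: dict[str, MetricsReport] = {}
    fused_labels: dict[str, list[Prediction]] = {}
    deltas: dict[str, float] = {}
    for s in strategies:
        if s == "max_confidence":
            out = [fuse_max_confidence(o, im) for o, im in zip(odour, image)]
        else:
            out = [
                fuse_majority([o, im, *per_sample])
                for o, im, *per_sample in zip(odour, image, *extra_voters)
            ]
        fused_labels[s] = out
        fused[s] = compute_metrics(out, labels)
        deltas[s] = fused[s].accuracy - best_unimodal

    return FusionResult(
        fused=fused,
        fused_labels=fused_labels,
        baselines=baselines,
        deltas=deltas,
        agreement=agreement_analysis(odour, image, labels),
    )
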