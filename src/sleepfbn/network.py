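"""Functional brain network construction from EEG segments.

Edges are absolute Pearson correlation coefficients |r| between band-passed
channel pairs, giving a weighted, unthresholded, symmetric adjacency over the
8 electrodes.  Negative correlations are treated as connectivity strength
(|r|, not r or r²).  One network per subject x timepoint is obtained by
element-wise averaging of the ten per-segment adjacencies; an optional
threshold/binarize pair is provided for sensitivity analyses only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateChannelError,
    IncompatibleNetworkError,
    InsufficientSamplesError,
    InvariantViolationError,
)


@dataclass
class FunctionalBrainNetwork:
    """Symmetric weighted adjacency over electrode nodes.

    Invariants enforced at construction: exact symmetry, exactly-zero
    diagonal, finite entries in [0, 1].
    """

    weights: np.ndarray
    node_labels: tuple
    n_segments_aggregated: int = 1
    subject_id: str = ""
    timepoint: str = ""

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.node_labels = tuple(self.node_labels)
        w = self.weights
        n = len(self.node_labels)
        if w.shape != (n, n):
            raise InvariantViolationError(f"weights shape {w.shape} != ({n}, {n})")
        if not np.all(np.isfinite(w)):
            raise InvariantViolationError("weights contain non-finite values")
        if not np.array_equal(w, w.T):
            raise InvariantViolationError("weights must be exactly symmetric")
        if np.any(np.diag(w) != 0):
            raise InvariantViolationError("diagonal must be exactly zero")
        if w.min() < 0 or w.max() > 1:
            raise InvariantViolationError("weights must lie in [0, 1]")

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)


def pearson_adjacency(
    segment: np.ndarray,
    node_labels=None,
    threshold: float = 0.0,
    binarize: bool = False,
    subject_id: str = "",
    timepoint: str = "",
) -> FunctionalBrainNetwork:
    """Absolute-Pearson-correlation adjacency of one channels x samples segment.

    ``weights[i, j] = |r(channel_i, channel_j)|`` with the diagonal zeroed.
    ``threshold`` sets weights below it to 0 and ``binarize`` maps surviving
    weights to 1; both default off (the pipeline analyses weighted,
    unthresholded networks).

    Raises
    ------
    InsufficientSamplesError
        Fewer than 3 samples or fewer than 2 channels.
    DegenerateChannelError
        Any constant channel (correlation undefined); the error names it.
    """
    segment = np.asarray(segment, dtype=float)
    n_ch, n_samp = segment.shape
    if n_samp < 3 or n_ch < 2:
        raise InsufficientSamplesError(
            f"need >= 2 channels and >= 3 samples, got {n_ch} x {n_samp}"
        )
    if node_labels is None:
        node_labels = tuple(f"ch{i + 1:02d}" for i in range(n_ch))
    sd = segment.std(axis=1)
    if np.any(sd == 0):
        bad = [node_labels[i] for i in np.flatnonzero(sd == 0)]
        raise DegenerateChannelError(f"constant channel(s): {', '.join(bad)}")
    r = np.corrcoef(segment)
    w = np.minimum(np.abs(r), 1.0)
    np.fill_diagonal(w, 0.0)
    if threshold > 0:
        w = np.where(w < threshold, 0.0, w)
    if binarize:
        w = (w > 0).astype(float)
    w = (w + w.T) / 2.0  # exact symmetry against floating-point asymmetry
    return FunctionalBrainNetwork(
        weights=w,
        node_labels=node_labels,
        n_segments_aggregated=1,
        subject_id=subject_id,
        timepoint=timepoint,
    )


def aggregate_networks(nets) -> FunctionalBrainNetwork:
    """Element-wise mean of a list of networks sharing node labels.

    This is the default aggregation: average the per-segment adjacencies
    first, then compute metrics on the mean network (one network per
    subject x timepoint).
    """
    nets = list(nets)
    if not nets:
        raise IncompatibleNetworkError("cannot aggregate an empty list of networks")
    labels = nets[0].node_labels
    for net in nets[1:]:
        if net.node_labels != labels:
            raise IncompatibleNetworkError(
                f"node labels differ: {net.node_labels} vs {labels}"
            )
    mean_w = np.mean([net.weights for net in nets], axis=0)
    mean_w = (mean_w + mean_w.T) / 2.0
    np.fill_diagonal(mean_w, 0.0)
    return FunctionalBrainNetwork(
        weights=mean_w,
        node_labels=labels,
        n_segments_aggregated=sum(net.n_segments_aggregated for net in nets),
        subject_id=nets[0].subject_id,
        timepoint=nets[0].timepoint,
    )


def segments_to_network(
    segs,
    threshold: float = 0.0,
    binarize: bool = False,
) -> FunctionalBrainNetwork:
    """Per-segment |PCC| adjacencies averaged into one network."""
    nets = [
        pearson_adjacency(
            seg,
            node_labels=segs.channel_labels,
            threshold=threshold,
            binarize=binarize,
            subject_id=segs.subject_id,
            timepoint=segs.timepoint,
        )
        for seg in segs.segments
    ]
    return aggregate_networks(nets)
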