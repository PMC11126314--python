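"""Montage transformations: common-average and bipolar re-referencing.

Both montages cancel any signal that is added identically to every channel
(machine-reference contamination): the common average subtracts the
per-sample mean over clean channels, and the bipolar montage differences
neighbouring contacts on the same depth electrode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .signals import ChannelInfo, Recording, format_channel_label

logger = logging.getLogger("connet")


class MontageError(ValueError):
    """Raised when a montage cannot be built from the retained channels."""


@dataclass
class DerivedChannel:
    """A bipolar derivative: lower-numbered contact minus the next retained
    contact on the same electrode (one missing contact may be skipped)."""

    name: str
    parents: tuple[ChannelInfo, ChannelInfo]

    @property
    def hemisphere(self) -> str:
        return self.parents[0].hemisphere

    @property
    def tissue(self) -> str:
        return self.parents[0].tissue

    @property
    def anchor_contact(self) -> ChannelInfo:
        return self.parents[0]


def _car_mask(rec: Recording) -> np.ndarray:
    # mean over artefact-free grey/white channels (CSF is already unretained)
    return np.array(
        [c.retained and c.tissue != "csf" for c in rec.channels], dtype=bool)


def common_average(rec: Recording) -> Recording:
    """Subtract the per-sample mean over retained channels; output contains
    only the retained channels and has exact zero mean at every sample."""
    mask = _car_mask(rec)
    if mask.sum() < 2:
        raise MontageError(
            f"common average needs >= 2 retained channels, got {int(mask.sum())}")
    sub = rec.data[mask]
    out = sub - sub.mean(axis=0, keepdims=True)
    channels = [c for c, m in zip(rec.channels, mask) if m]
    return Recording(data=out, fs=rec.fs, channels=channels, scheme="car",
                     epoch_start=rec.epoch_start)


def bipolar_pairs(channels: list[ChannelInfo], max_skip: int = 1) -> list[DerivedChannel]:
    """Pair retained contacts with the next retained contact on the same
    electrode when the index gap is at most ``max_skip + 1``.

    LA01, LA02, LA03 -> LA01-LA02, LA02-LA03; with LA02 missing, LA01-LA03 is
    allowed (one skipped contact by default). Pairs never cross electrodes.
    """
    by_electrode: dict[str, list[ChannelInfo]] = {}
    for ch in channels:
        if ch.retained:
            by_electrode.setdefault(ch.electrode, []).append(ch)
    pairs: list[DerivedChannel] = []
    for elec, chans in by_electrode.items():
        chans = sorted(chans, key=lambda c: c.contact_index)
        if len(chans) < 2:
            logger.info("bipolar_pairs: electrode %s has a single retained "
                        "contact; no pairs", elec)
            continue
        for a, b in zip(chans[:-1], chans[1:]):
            if b.contact_index - a.contact_index <= max_skip + 1:
                pairs.append(DerivedChannel(name=f"{a.label}-{b.label}",
                                            parents=(a, b)))
    return pairs


def bipolar(rec: Recording, max_skip: int = 1) -> Recording:
    """Build the bipolar montage: each derived signal is the lower-numbered
    parent minus the higher-numbered parent."""
    pairs = bipolar_pairs(rec.channels, max_skip=max_skip)
    if not pairs:
        raise MontageError("no bipolar pairs can be formed from retained channels")
    idx = {c.label: i for i, c in enumerate(rec.channels)}
    data = np.stack([rec.data[idx[p.parents[0].label]]
                     - rec.data[idx[p.parents[1].label]] for p in pairs])
    channels = [
        ChannelInfo(label=p.name, electrode=p.parents[0].electrode,
                    contact_index=p.parents[0].contact_index,
                    hemisphere=p.hemisphere, tissue=p.tissue, retained=True)
        for p in pairs
    ]
    return Recording(data=data, fs=rec.fs, channels=channels, scheme="bipolar",
                     epoch_start=rec.epoch_start)


def apply_reference(rec: Recording, scheme: str, max_skip: int = 1) -> Recording:
    """Dispatch: machine (identity), car, or bipolar."""
    if scheme == "machine":
        return rec
    if scheme == "car":
        return common_average(rec)
    if scheme == "bipolar":
        return bipolar(rec, max_skip=max_skip)
    raise MontageError(f"unknown reference scheme {scheme!r}")


def anchor_label(node_name: str) -> str:
    """Map a node name to its anchor contact label: bipolar derivatives map to
    their lower-numbered parent ("LA01-LA02" -> "LA01"), plain contacts map to
    their canonical 2-digit form."""
    from .signals import LabelError, parse_channel_label

    try:  # plain contact label (hyphen, if any, is a separator: "LA-01")
        elec, idx = parse_channel_label(node_name)
    except LabelError:
        elec, idx = parse_channel_label(node_name.split("-", 1)[0])
    return format_channel_label(elec, idx)
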