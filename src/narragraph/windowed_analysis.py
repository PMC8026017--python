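"""Verbosity control via moving windows.

Graph attributes grow mechanically with narrative length, so attributes
are computed on fixed-length overlapping token windows (default 30
tokens, 50% overlap) and averaged per narrative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

from .graph_core import ATTRIBUTE_NAMES, GraphAttributes, compute_attributes
from .text_processing import TokenSequence

__all__ = [
    "WindowConfig",
    "NarrativeProfile",
    "EmptyNarrativeError",
    "make_windows",
    "profile_narrative",
]


class EmptyNarrativeError(ValueError):
    """Raised when a narrative has no tokens left after cleaning."""


@dataclass(frozen=True)
class WindowConfig:
    """Moving-window parameters.

    ``step`` is ``round(window_length * (1 - overlap_fraction))``,
    floored at 1.  Trailing tokens not covered by a final full window are
    dropped unless ``include_trailing`` adds an end-anchored window.
    """

    window_length: int = 30
    overlap_fraction: float = 0.5
    include_trailing: bool = False
    tnw_source: Literal["cleaned", "raw"] = "cleaned"

    def __post_init__(self) -> None:
        if self.window_length < 2:
            raise ValueError("window_length must be >= 2")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in [0, 1)")

    @property
    def step(self) -> int:
        return max(1, round(self.window_length * (1.0 - self.overlap_fraction)))


@dataclass(frozen=True)
class NarrativeProfile:
    """Windowed attribute means plus verbosity for one narrative."""

    subject_id: str
    tnw: int
    window_count: int
    mean_attributes: dict[str, float]

    def as_row(self) -> dict[str, float]:
        row: dict[str, float] = {
            "subject_id": self.subject_id,
            "TNW": self.tnw,
            "window_count": self.window_count,
        }
        row.update(self.mean_attributes)
        return row


def make_windows(
    tokens: Sequence[str], cfg: WindowConfig = WindowConfig()
) -> list[Sequence[str]]:
    """Full-length moving windows over a token sequence.

    Windows start at 0, step, 2*step, ...; only full windows are emitted.
    A sequence shorter than the window length yields a single window
    containing all tokens.
    """
    if not tokens:
        raise EmptyNarrativeError("cannot window an empty token sequence")
    length = len(tokens)
    w = cfg.window_length
    if length < w:
        return [tokens[:]]
    step = cfg.step
    windows = [tokens[s : s + w] for s in range(0, length - w + 1, step)]
    if cfg.include_trailing and (length - w) % step != 0:
        windows.append(tokens[length - w :])
    return windows


def profile_narrative(
    seq: TokenSequence, cfg: WindowConfig = WindowConfig(), **attr_kwargs
) -> NarrativeProfile:
    """Unweighted mean of per-window attributes for one narrative.

    TNW is the cleaned token count by default (``cfg.tnw_source="raw"``
    switches to the pre-stop-word count).  Extra keyword arguments are
    forwarded to :func:`narragraph.graph_core.compute_attributes`.
    """
    if len(seq.tokens) == 0:
        raise EmptyNarrativeError(
            f"narrative {seq.subject_id!r} has no tokens after cleaning"
        )
    windows = make_windows(list(seq.tokens), cfg)
    per_window = [compute_attributes(w, **attr_kwargs) for w in windows]
    means = {
        name: sum(getattr(a, name) for a in per_window) / len(per_window)
        for name in ATTRIBUTE_NAMES
    }
    tnw = len(seq.tokens) if cfg.tnw_source == "cleaned" else seq.raw_token_count
    return NarrativeProfile(
        subject_id=seq.subject_id,
        tnw=tnw,
        window_count=len(windows),
        mean_attributes=means,
    )
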