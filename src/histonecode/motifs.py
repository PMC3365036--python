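"""Flanking-sequence analysis around modified sites.

Fixed-width windows (default 11 residues: five on either side of the
modified residue) are cut from the reference around each modified site,
summarised as a position-frequency matrix, and searched for
over-represented fixed-position motifs by a greedy motif-x-style
procedure: at each step the (offset, residue) pair whose foreground count
is most surprising under a binomial null (success probability = that
residue's frequency at that offset in a histone-only background) is fixed
into the pattern, both window sets are filtered to the matching windows,
and the process repeats; once a motif terminates, its matching foreground
windows are removed and extraction restarts for the next motif.

Patterns are serialised with ``.`` wildcards and a lowercase centre
letter, e.g. ``.....kA..K.`` for acetyl-K followed by Ala at +1 and Lys
at +5.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import PtmType
from .reference import AMINO_ACIDS, HistoneReference

PAD = "-"


@dataclass(frozen=True)
class SiteWindow:
    """A (2w+1)-residue window centred on a modified site; ``-`` pads ends."""

    residues: str
    center_ptm: PtmType | None = None

    def __post_init__(self) -> None:
        if len(self.residues) % 2 != 1:
            raise ValueError("window length must be odd")

    @property
    def half_width(self) -> int:
        return len(self.residues) // 2

    @property
    def center(self) -> str:
        return self.residues[self.half_width]


def extract_windows(
    sites: Iterable[tuple[str, int, PtmType]],
    references: Mapping[str, HistoneReference],
    w: int = 5,
) -> list[SiteWindow]:
    """Cut a window of half-width ``w`` around each (histone, position, ptm) site."""
    windows = []
    for histone, position, ptm in sites:
        ref = references[histone]
        ref.residue(position)  # validates the position
        chars = []
        for offset in range(-w, w + 1):
            pos = position + offset
            chars.append(ref.sequence[pos - 1] if 1 <= pos <= len(ref) else PAD)
        windows.append(SiteWindow("".join(chars), center_ptm=ptm))
    return windows


def build_background(
    references: Mapping[str, HistoneReference], center_residue: str, w: int = 5
) -> list[SiteWindow]:
    """One window per occurrence of ``center_residue`` across all references."""
    if center_residue not in AMINO_ACIDS:
        raise ValueError(f"invalid amino acid {center_residue!r}")
    windows = []
    for ref in references.values():
        for i, aa in enumerate(ref.sequence, start=1):
            if aa == center_residue:
                chars = [
                    ref.sequence[i + off - 1] if 1 <= i + off <= len(ref) else PAD
                    for off in range(-w, w + 1)
                ]
                windows.append(SiteWindow("".join(chars)))
    if not windows:
        raise ValueError(
            f"residue {center_residue!r} never occurs in the reference set"
        )
    return windows


def frequency_matrix(windows: Sequence[SiteWindow]) -> pd.DataFrame:
    """Per-offset residue frequencies; pads excluded from both counts and totals.

    Rows are amino acids, columns are offsets -w..+w; each column sums to 1.
    """
    if not windows:
        raise ValueError("cannot build a frequency matrix from zero windows")
    w = windows[0].half_width
    if any(win.half_width != w for win in windows):
        raise ValueError("windows differ in width")
    offsets = list(range(-w, w + 1))
    aas = sorted(AMINO_ACIDS)
    counts = np.zeros((len(aas), len(offsets)), dtype=float)
    aa_index = {aa: i for i, aa in enumerate(aas)}
    for win in windows:
        for j, ch in enumerate(win.residues):
            if ch != PAD:
                counts[aa_index[ch], j] += 1
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("an offset column contains only padding")
    return pd.DataFrame(counts / totals, index=aas, columns=offsets)


@dataclass(frozen=True)
class MotifResult:
    """A fixed-position motif with its enrichment against the background."""

    pattern: str
    fixed: tuple[tuple[int, str], ...]  # (offset, residue) pairs, in fixing order
    support_count: int
    fold_enrichment: float
    p_value: float
    step_p_values: tuple[float, ...]


def _binomial_tail(k: int, n: int, p: float) -> float:
    """P[X >= k] for X ~ Binomial(n, p)."""
    if k <= 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p))


def _matches(window: SiteWindow, fixed: Sequence[tuple[int, str]], w: int) -> bool:
    return all(window.residues[off + w] == aa for off, aa in fixed)


def find_motifs(
    foreground: Sequence[SiteWindow],
    background: Sequence[SiteWindow],
    min_count: int = 5,
    p_threshold: float = 1e-6,
    max_motifs: int = 20,
) -> list[MotifResult]:
    """Greedy iterative extraction of over-represented fixed-position motifs.

    The centre offset is never fixed (all windows share the centre residue
    class).  A motif is reported once at least one position has been fixed;
    its matching foreground windows are removed before the next motif is
    sought.  Fold enrichment compares foreground and background match
    fractions of the full pattern.
    """
    if not foreground:
        return []
    w = foreground[0].half_width
    if any(win.half_width != w for win in list(foreground) + list(background)):
        raise ValueError("foreground/background windows differ in width")
    center = foreground[0].center
    remaining = list(foreground)
    motifs: list[MotifResult] = []
    while len(motifs) < max_motifs and len(remaining) >= min_count:
        fg = list(remaining)
        bg = list(background)
        fixed: list[tuple[int, str]] = []
        step_ps: list[float] = []
        while True:
            best = None
            n = len(fg)
            if n < min_count or not bg:
                break
            fixed_offsets = {off for off, _ in fixed}
            for off in range(-w, w + 1):
                if off == 0 or off in fixed_offsets:
                    continue
                fg_counts: dict[str, int] = {}
                for win in fg:
                    ch = win.residues[off + w]
                    if ch != PAD:
                        fg_counts[ch] = fg_counts.get(ch, 0) + 1
                bg_total = sum(1 for win in bg if win.residues[off + w] != PAD)
                if bg_total == 0:
                    continue
                for aa, k in fg_counts.items():
                    if k < min_count:
                        continue
                    p_bg = sum(1 for win in bg if win.residues[off + w] == aa) / bg_total
                    # a residue absent from the background cannot be scored
                    if p_bg == 0.0:
                        continue
                    p_val = _binomial_tail(k, n, p_bg)
                    cand = (p_val, off, aa, k)
                    if best is None or cand < best:
                        best = cand
            if best is None or best[0] > p_threshold:
                break
            p_val, off, aa, _k = best
            fixed.append((off, aa))
            step_ps.append(p_val)
            fg = [win for win in fg if win.residues[off + w] == aa]
            bg = [win for win in bg if win.residues[off + w] == aa]
        if not fixed:
            break
        n_match = len(fg)
        fg_frac = n_match / len(remaining)
        bg_match = sum(1 for win in background if _matches(win, fixed, w))
        bg_frac = bg_match / len(background) if background else 0.0
        fold = fg_frac / bg_frac if bg_frac > 0 else float("inf")
        motifs.append(
            MotifResult(
                pattern=serialise_pattern(fixed, center, w),
                fixed=tuple(fixed),
                support_count=n_match,
                fold_enrichment=fold,
                p_value=step_ps[-1],
                step_p_values=tuple(step_ps),
            )
        )
        remaining = [win for win in remaining if not _matches(win, fixed, w)]
    return motifs


def serialise_pattern(
    fixed: Sequence[tuple[int, str]], center: str, w: int
) -> str:
    """Dot-wildcard pattern with a lowercase centre, e.g. ``.....kA..K.``."""
    chars = ["."] * (2 * w + 1)
    chars[w] = center.lower()
    for off, aa in fixed:
        chars[off + w] = aa
    return "".join(chars)


def windows_to_fasta(path: str | Path, windows: Sequence[SiteWindow]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i, win in enumerate(windows):
            tag = win.center_ptm.name if win.center_ptm else "site"
            fh.write(f">window_{i}_{tag}\n{win.residues}\n")


def motifs_to_frame(motifs: Sequence[MotifResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pattern": [m.pattern for m in motifs],
            "count": [m.support_count for m in motifs],
            "fold_enrichment": [m.fold_enrichment for m in motifs],
            "p_value": [m.p_value for m in motifs],
        }
    )
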