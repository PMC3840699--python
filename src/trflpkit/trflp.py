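"""In-silico terminal restriction fragment analysis.

Predicts the fluorescently labelled terminal fragments produced by digesting
primer-delimited amplicons with a restriction enzyme, assembles per-sample
electropherogram peak profiles from community abundance vectors, and bins the
profiles into a standardized fingerprint matrix.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "Amplicon",
    "TerminalFragment",
    "PeakProfile",
    "FingerprintMatrix",
    "AmpliconError",
    "iupac_regex",
    "revcomp",
    "find_amplicon",
    "terminal_fragment",
    "digest_amplicons",
    "profile_sample",
    "bin_and_standardize",
    "HHAI_SITE",
    "HHAI_CUT_OFFSET",
]

# HhaI recognizes GCGC and cuts GCG^C: 3 bases into the site.
HHAI_SITE = "GCGC"
HHAI_CUT_OFFSET = 3

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class AmpliconError(ValueError):
    """Raised when primers fail to delimit a unique product."""


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC DNA string (case-insensitive)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def iupac_regex(pattern: str) -> re.Pattern:
    """Compile an IUPAC DNA string into a regex with degenerate codes
    expanded to character classes."""
    parts = []
    for base in pattern.upper():
        try:
            exp = _IUPAC[base]
        except KeyError:
            raise ValueError(f"invalid IUPAC code {base!r} in {pattern!r}")
        parts.append(base if len(exp) == 1 else f"[{exp}]")
    return re.compile("".join(parts))


@dataclass(frozen=True)
class Amplicon:
    """A primer-delimited PCR product, 5'→3' top strand.

    The sequence begins with the forward-primer site and ends with the
    reverse complement of the reverse primer.
    """

    otu_id: str
    residues: str
    fwd_label: str = "FAM"
    rev_label: str = "JOE"

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class TerminalFragment:
    """Length of the labelled terminal fragment on one channel.

    ``cut`` is False for a pseudo-T-RF: no site was found and the whole
    amplicon migrates as one fragment.
    """

    length: int
    channel: str  # "forward" | "reverse"
    cut: bool = True

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("fragment length must be >= 1")
        if self.channel not in ("forward", "reverse"):
            raise ValueError(f"unknown channel {self.channel!r}")


@dataclass
class PeakProfile:
    """One sample's electropherogram on one dye channel as (size, height)."""

    sample_id: str
    channel: str
    peaks: List[Tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        sizes = [s for s, _ in self.peaks]
        if sizes != sorted(sizes) or len(set(sizes)) != len(sizes):
            raise ValueError("peak sizes must be strictly increasing")
        for _, h in self.peaks:
            if not np.isfinite(h) or h < 0:
                raise ValueError("peak heights must be finite and >= 0")


@dataclass
class FingerprintMatrix:
    """Samples x T-RF bins of relative peak heights (rows sum to 1)."""

    sample_ids: List[str]
    bin_centers: List[float]
    bin_width: float
    values: np.ndarray  # shape (n_samples, n_bins)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.bin_centers
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, bin_width: float = 1.0) -> "FingerprintMatrix":
        return cls(
            sample_ids=[str(i) for i in df.index],
            bin_centers=[float(c) for c in df.columns],
            bin_width=bin_width,
            values=df.to_numpy(dtype=float),
        )


def find_amplicon(
    template: str,
    fwd_primer: str,
    rev_primer: str,
    otu_id: str = "",
    multiple: str = "first",
) -> Amplicon:
    """Locate the PCR product delimited by a primer pair on the top strand.

    The product runs from the first match of ``fwd_primer`` (inclusive)
    through the first downstream match of the reverse complement of
    ``rev_primer`` (inclusive). Primer matching is exact with IUPAC
    degeneracies expanded; no mismatches are tolerated.

    Parameters
    ----------
    multiple:
        "first" returns the first product when further reverse-primer sites
        exist downstream; "error" raises :class:`AmpliconError` instead.
    """
    if len(fwd_primer) < 4 or len(rev_primer) < 4:
        raise ValueError("primers must be at least 4 bp")
    template = template.upper()
    fm = iupac_regex(fwd_primer).search(template)
    if fm is None:
        raise AmpliconError(f"forward primer {fwd_primer!r} not found")
    rev_rc = revcomp(rev_primer)
    matches = list(iupac_regex(rev_rc).finditer(template, fm.end()))
    if not matches:
        raise AmpliconError(
            f"reverse-primer site {rev_rc!r} not found downstream of forward match"
        )
    if len(matches) > 1 and multiple == "error":
        raise AmpliconError(f"{len(matches)} candidate products (ambiguous)")
    return Amplicon(otu_id=otu_id, residues=template[fm.start(): matches[0].end()])


def terminal_fragment(
    amplicon: Amplicon,
    site: str = HHAI_SITE,
    cut_offset: int = HHAI_CUT_OFFSET,
    channel: str = "forward",
) -> TerminalFragment:
    """Length of the labelled terminal fragment after digestion.

    Forward channel: distance from the 5' end of the top strand to the cut
    within the first site occurrence. Reverse channel: the same computation
    on the reverse-complement strand. If no site occurs the amplicon is
    uncut and reported as a pseudo-T-RF of full length.
    """
    if len(site) < 1:
        raise ValueError("site must be at least 1 bp")
    if not 0 <= cut_offset <= len(site):
        raise ValueError("cut_offset must lie within the site")
    if channel == "forward":
        strand = amplicon.residues.upper()
    elif channel == "reverse":
        strand = revcomp(amplicon.residues)
    else:
        raise ValueError(f"unknown channel {channel!r}")
    m = iupac_regex(site).search(strand)
    if m is None:
        return TerminalFragment(length=len(strand), channel=channel, cut=False)
    return TerminalFragment(length=m.start() + cut_offset, channel=channel, cut=True)


def digest_amplicons(
    amplicons: Iterable[Amplicon],
    site: str = HHAI_SITE,
    cut_offset: int = HHAI_CUT_OFFSET,
) -> pd.DataFrame:
    """Digest a collection of amplicons on both channels.

    Returns a tidy frame with columns ``otu_id, channel, length_bp, cut``.
    """
    rows = []
    for amp in amplicons:
        for channel in ("forward", "reverse"):
            tf = terminal_fragment(amp, site=site, cut_offset=cut_offset, channel=channel)
            rows.append(
                {"otu_id": amp.otu_id, "channel": channel,
                 "length_bp": tf.length, "cut": tf.cut}
            )
    return pd.DataFrame(rows, columns=["otu_id", "channel", "length_bp", "cut"])


def profile_sample(
    community: Mapping[str, float],
    fragments: Mapping[str, TerminalFragment],
    sample_id: str = "sample",
    scale: float = 1000.0,
    noise_cv: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    drop_uncut: bool = False,
) -> PeakProfile:
    """Map a relative-abundance vector to an electropherogram peak profile.

    OTUs whose fragments share a length co-migrate into a single peak whose
    height is ``scale`` times the summed abundance, perturbed by mean-one
    lognormal noise with coefficient of variation ``noise_cv``.
    """
    if scale < 0:
        raise ValueError("scale must be non-negative")
    total = sum(community.values())
    if community and not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"community abundances must sum to 1 (got {total})")
    heights: Dict[Tuple[int, str], float] = {}
    channel = None
    for otu_id, ab in community.items():
        frag = fragments[otu_id]
        if drop_uncut and not frag.cut:
            continue
        channel = channel or frag.channel
        if frag.channel != channel:
            raise ValueError("all fragments in one profile must share a channel")
        heights[(frag.length, frag.channel)] = (
            heights.get((frag.length, frag.channel), 0.0) + ab * scale
        )
    if noise_cv > 0:
        rng = rng if rng is not None else np.random.default_rng()
        sigma = np.sqrt(np.log1p(noise_cv**2))
        for key in sorted(heights):
            heights[key] *= rng.lognormal(mean=-sigma**2 / 2, sigma=sigma)
    peaks = sorted((float(length), h) for (length, _), h in heights.items())
    return PeakProfile(sample_id=sample_id, channel=channel or "forward", peaks=peaks)


def bin_and_standardize(
    profiles: Sequence[PeakProfile],
    bin_width: float = 1.0,
    size_min: float = 34.0,
    size_max: float = 966.0,
    rel_threshold: float = 0.0,
) -> FingerprintMatrix:
    """Bin peak profiles into a standardized fingerprint matrix.

    Peaks outside ``[size_min, size_max]`` are discarded; the rest fall into
    half-open bins ``[size_min + k*w, size_min + (k+1)*w)`` anchored at
    ``size_min``. Heights are converted to within-sample fractions, bins
    below ``rel_threshold`` are zeroed per sample, rows renormalized, and
    bins empty in every sample dropped.
    """
    if size_min >= size_max:
        raise ValueError("size_min must be < size_max")
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    n_bins = int(np.ceil((size_max - size_min + 1e-9) / bin_width))
    mat = np.zeros((len(profiles), n_bins))
    for i, prof in enumerate(profiles):
        for size, height in prof.peaks:
            if size < size_min or size > size_max:
                continue
            k = min(int((size - size_min) // bin_width), n_bins - 1)
            mat[i, k] += height
    row_sums = mat.sum(axis=1, keepdims=True)
    if np.all(row_sums == 0):
        warnings.warn("all peaks filtered out in every sample; matrix is all-zero")
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(row_sums > 0, mat / row_sums, 0.0)
    if rel_threshold > 0:
        frac[frac < rel_threshold] = 0.0
        row_sums = frac.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(row_sums > 0, frac / row_sums, 0.0)
    keep = frac.sum(axis=0) > 0
    centers = size_min + (np.arange(n_bins) + 0.5) * bin_width
    return FingerprintMatrix(
        sample_ids=[p.sample_id for p in profiles],
        bin_centers=[float(c) for c in centers[keep]],
        bin_width=float(bin_width),
        values=frac[:, keep],
    )
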