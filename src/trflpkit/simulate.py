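"""Synthetic deep-ocean transect scenarios.

Generates ground-truth community scenarios with the statistical structure the
downstream analyses assume: depth-stratified communities tied to water-mass
groups, per-layer environmental envelopes, a configurable fraction of
ubiquitous and group-unique OTUs, and a gradual along-path community turnover
confined to exactly one water mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .trflp import HHAI_CUT_OFFSET, HHAI_SITE, revcomp

__all__ = [
    "ScenarioConfig",
    "SampleMetadata",
    "TransectScenario",
    "ConfigurationError",
    "LAYER_ENVELOPES",
    "DEFAULT_LAYERS",
    "DEFAULT_LAYER_GROUPS",
    "BACTERIAL_FWD_PRIMER",
    "BACTERIAL_REV_PRIMER",
    "ARCHAEAL_FWD_PRIMER",
    "ARCHAEAL_REV_PRIMER",
    "generate_otu_sequences",
    "generate_scenario",
    "sample_clone_library",
]

# 16S primer pairs: universal bacterial 27F/1492R, archaeal 21F/958R.
BACTERIAL_FWD_PRIMER = "AGAGTTTGATCMTGGCTCAG"
BACTERIAL_REV_PRIMER = "GGTTACCTTGTTACGACTT"
ARCHAEAL_FWD_PRIMER = "TTCCGGTTGATCCYGCCGGA"
ARCHAEAL_REV_PRIMER = "YCCGGCGTTGAMTCCAATT"

DEFAULT_LAYERS = [
    "Subsurface", "SACW-OMZ", "SACW", "AAIW", "uNADW", "mNADW", "lNADW", "AABW",
]

DEFAULT_LAYER_GROUPS = {
    "Subsurface": "Subsurface",
    "SACW-OMZ": "SACW",
    "SACW": "SACW",
    "AAIW": "AAIW",
    "uNADW": "NADW",
    "mNADW": "NADW",
    "lNADW": "NADW",
    "AABW": "AABW",
}

# Per-layer environmental envelopes: (low, high) for each variable.
# Values are uniform draws within the envelope, so scenario metadata always
# stays inside the configured ranges.
LAYER_ENVELOPES: Dict[str, Dict[str, Tuple[float, float]]] = {
    "Subsurface": {
        "depth_m": (90, 110), "temperature_c": (14.2, 15.9),
        "salinity": (35.4, 35.7), "oxygen": (100.9, 170.3),
        "nitrate": (11.03, 22.09), "nitrite": (0.03, 0.13),
        "ammonia": (0.00, 0.01), "phosphate": (0.84, 1.41),
        "silicate": (4.31, 7.14),
    },
    "SACW-OMZ": {
        "depth_m": (240, 260), "temperature_c": (11.0, 12.5),
        "salinity": (35.1, 35.2), "oxygen": (84.3, 106.2),
        "nitrate": (24.20, 29.43), "nitrite": (0.01, 0.02),
        "ammonia": (0.00, 0.02), "phosphate": (1.55, 1.83),
        "silicate": (9.30, 11.79),
    },
    "SACW": {
        "depth_m": (480, 520), "temperature_c": (6.4, 7.7),
        "salinity": (34.5, 34.6), "oxygen": (131.1, 168.6),
        "nitrate": (29.81, 30.93), "nitrite": (0.01, 0.01),
        "ammonia": (0.01, 0.01), "phosphate": (2.01, 2.03),
        "silicate": (18.22, 19.08),
    },
    "AAIW": {
        "depth_m": (720, 780), "temperature_c": (4.7, 5.1),
        "salinity": (34.4, 34.5), "oxygen": (145.5, 165.1),
        "nitrate": (33.20, 34.42), "nitrite": (0.0, 0.01),
        "ammonia": (0.01, 0.01), "phosphate": (2.23, 2.32),
        "silicate": (27.65, 29.31),
    },
    "uNADW": {
        "depth_m": (1650, 1850), "temperature_c": (3.8, 4.0),
        "salinity": (35.0, 35.0), "oxygen": (235.2, 247.6),
        "nitrate": (19.28, 20.21), "nitrite": (0.0, 0.01),
        "ammonia": (0.00, 0.01), "phosphate": (1.27, 1.33),
        "silicate": (16.21, 17.71),
    },
    "mNADW": {
        "depth_m": (2650, 2850), "temperature_c": (2.4, 2.8),
        "salinity": (34.9, 35.0), "oxygen": (238.1, 246.6),
        "nitrate": (20.76, 21.71), "nitrite": (0.0, 0.01),
        "ammonia": (0.01, 0.01), "phosphate": (1.37, 1.45),
        "silicate": (30.94, 40.92),
    },
    "lNADW": {
        "depth_m": (3750, 4000), "temperature_c": (2.1, 2.4),
        "salinity": (34.9, 34.9), "oxygen": (245.2, 254.2),
        "nitrate": (19.56, 21.42), "nitrite": (0.0, 0.01),
        "ammonia": (0.01, 0.01), "phosphate": (1.32, 1.48),
        "silicate": (32.61, 45.18),
    },
    "AABW": {
        "depth_m": (4500, 7000), "temperature_c": (1.0, 1.4),
        "salinity": (34.8, 34.8), "oxygen": (222.9, 229.0),
        "nitrate": (27.19, 29.26), "nitrite": (0.01, 0.12),
        "ammonia": (0.01, 0.01), "phosphate": (1.86, 2.01),
        "silicate": (82.74, 94.47),
    },
}

ENV_VARIABLES = [
    "temperature_c", "salinity", "oxygen", "nitrate", "nitrite",
    "ammonia", "phosphate", "silicate",
]


class ConfigurationError(ValueError):
    """Raised for infeasible scenario configurations."""


@dataclass(frozen=True)
class ScenarioConfig:
    """All knobs of the synthetic transect generator."""

    n_stations_transect: int = 18
    n_stations_offpath: int = 9
    layers: Tuple[str, ...] = tuple(DEFAULT_LAYERS)
    layer_groups: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_LAYER_GROUPS)
    )
    otu_pool_size: int = 116
    frac_ubiquitous: float = 0.18
    frac_unique: float = 0.22
    succession_layer: str = "NADW"  # a layer-group label
    succession_rate: float = 4.0e-4  # fractional turnover per km
    abundance_model: str = "lognormal"
    abundance_sigma: float = 1.0
    noise_cv: float = 0.05
    transect_length_km: float = 2000.0
    amplicon_length: int = 1400
    trf_range: Tuple[int, int] = (34, 966)
    fwd_primer: str = BACTERIAL_FWD_PRIMER
    rev_primer: str = BACTERIAL_REV_PRIMER
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stations_transect < 2:
            raise ConfigurationError("need at least 2 transect stations")
        if self.n_stations_offpath < 0:
            raise ConfigurationError("n_stations_offpath must be >= 0")
        if not (0 <= self.frac_ubiquitous <= 1 and 0 <= self.frac_unique <= 1):
            raise ConfigurationError("sharing fractions must lie in [0, 1]")
        if self.frac_ubiquitous + self.frac_unique > 1 + 1e-12:
            raise ConfigurationError(
                "frac_ubiquitous + frac_unique must not exceed 1"
            )
        if self.otu_pool_size < len(self.layers):
            raise ConfigurationError("otu_pool_size must be >= number of layers")
        if self.succession_rate < 0 or self.noise_cv < 0:
            raise ConfigurationError("rates must be >= 0")
        if self.abundance_model not in ("lognormal", "logseries"):
            raise ConfigurationError(
                f"unknown abundance model {self.abundance_model!r}"
            )
        missing = [l for l in self.layers if l not in self.layer_groups]
        if missing:
            raise ConfigurationError(f"layers without a group: {missing}")

    @property
    def groups(self) -> List[str]:
        """Distinct layer-group labels in layer order."""
        out: List[str] = []
        for layer in self.layers:
            g = self.layer_groups[layer]
            if g not in out:
                out.append(g)
        return out


@dataclass(frozen=True)
class SampleMetadata:
    """Environmental record for one sample (station x layer)."""

    sample_id: str
    station: int
    layer: str
    group: str
    region: str
    depth_m: float
    along_path_km: float
    temperature_c: float
    salinity: float
    oxygen: float
    nitrate: float
    nitrite: float
    ammonia: float
    phosphate: float
    silicate: float
    prokaryotic_abundance: Optional[float] = None
    leucine_incorporation: Optional[float] = None


@dataclass
class TransectScenario:
    """Ground truth produced by :func:`generate_scenario`."""

    config: ScenarioConfig
    otu_ids: List[str]
    otu_sequences: Dict[str, str]
    # abundance[s, l, o]: relative abundance of OTU o in layer l at station s
    abundance: np.ndarray
    stations: List[int]
    layers: List[str]
    metadata: pd.DataFrame
    layout: pd.DataFrame
    membership: pd.DataFrame  # otu_id, flag, groups (";"-joined)
    base_communities: Dict[str, np.ndarray]
    alt_communities: Dict[str, np.ndarray]

    def community(self, station: int, layer: str) -> Dict[str, float]:
        s = self.stations.index(station)
        l = self.layers.index(layer)
        vec = self.abundance[s, l]
        return {o: float(v) for o, v in zip(self.otu_ids, vec) if v > 0}

    def abundance_long(self) -> pd.DataFrame:
        rows = []
        for s, st in enumerate(self.stations):
            for l, layer in enumerate(self.layers):
                vec = self.abundance[s, l]
                for o, v in zip(self.otu_ids, vec):
                    if v > 0:
                        rows.append((st, layer, o, v))
        return pd.DataFrame(
            rows, columns=["station", "layer", "otu_id", "rel_abundance"]
        )

    def expected_decay_slope(self, group: Optional[str] = None) -> float:
        """Analytic expected distance-decay slope (percent per km) of the
        noise-free Bray-Curtis similarity to the reference station, for the
        succession group.

        With community(d) = (1-f(d))*base + f(d)*alt and f(d) = rate*d,
        similarity to the reference is 100*(1 - f(d)*D/2) where
        D = sum(|base-alt|), hence the slope is -100*rate*D/2, averaged over
        the group's sub-layers. Valid while f(d) <= 1 across the transect.
        """
        group = group or self.config.succession_layer
        if group != self.config.succession_layer or not self.alt_communities:
            return 0.0
        slopes = []
        for layer, base in self.base_communities.items():
            if self.config.layer_groups[layer] != group:
                continue
            alt = self.alt_communities[layer]
            d = np.abs(base - alt).sum()
            slopes.append(-100.0 * self.config.succession_rate * d / 2.0)
        return float(np.mean(slopes)) if slopes else 0.0


def _find_site(seq: str, site: str) -> int:
    return seq.find(site)


def _concretize(primer: str, rng: np.random.Generator) -> str:
    """Replace degenerate IUPAC codes with a fixed concrete base."""
    from .trflp import _IUPAC  # shared code table

    return "".join(_IUPAC[b][0] for b in primer.upper())


def generate_otu_sequences(
    n: int,
    length: int = 1400,
    trf_range: Tuple[int, int] = (34, 966),
    seed: int = 0,
    fwd_primer: str = BACTERIAL_FWD_PRIMER,
    rev_primer: str = BACTERIAL_REV_PRIMER,
    site: str = HHAI_SITE,
    cut_offset: int = HHAI_CUT_OFFSET,
    otu_prefix: str = "OTU",
) -> Dict[str, str]:
    """Generate n primer-flanked OTU sequences with distinct forward T-RFs.

    Each sequence starts with the (concretized) forward-primer site, ends
    with the reverse complement of the reverse primer, and carries its first
    restriction site exactly where the drawn target T-RF length dictates, so
    every OTU is resolvable by its forward terminal fragment.
    """
    rng = np.random.default_rng(seed)
    prefix = _concretize(fwd_primer, rng)
    suffix = revcomp(_concretize(rev_primer, rng))
    if site in prefix or site in suffix:
        raise ConfigurationError("primer regions must not contain the enzyme site")
    lo, hi = trf_range
    # site must fit in the free region with >=3 mutable bases upstream so
    # junction-straddling occurrences can always be repaired
    min_len = max(lo, len(prefix) + cut_offset + 3)
    max_len = min(hi, length - len(suffix) - len(site) + cut_offset)
    achievable = max(0, max_len - min_len + 1)
    n_range = hi - lo + 1
    if n > min(achievable, n_range):
        raise ConfigurationError(
            f"cannot place {n} distinct T-RF lengths: only "
            f"{min(achievable, n_range)} distinct lengths achievable in "
            f"{trf_range} for amplicon length {length}"
        )
    targets = rng.choice(np.arange(min_len, max_len + 1), size=n, replace=False)
    bases = np.array(list("ACGT"))
    sequences: Dict[str, str] = {}
    width = len(str(n))
    for i, target in enumerate(sorted(int(t) for t in targets)):
        s = target - cut_offset  # site start index
        seq = list(prefix)
        seq += list(rng.choice(bases, size=length - len(prefix) - len(suffix)))
        seq += list(suffix)
        seq[s: s + len(site)] = list(site)
        protected = set(range(len(prefix))) | set(range(s, s + len(site)))
        for _ in range(10_000):
            first = _find_site("".join(seq), site)
            if first == s:
                break
            # mutate one mutable base inside the spurious occurrence
            candidates = [
                j for j in range(first, first + len(site)) if j not in protected
            ]
            j = int(rng.choice(candidates))
            seq[j] = str(rng.choice(bases[bases != seq[j]]))
        else:  # pragma: no cover - does not occur in practice
            raise RuntimeError("failed to repair spurious enzyme sites")
        sequences[f"{otu_prefix}{i + 1:0{width}d}"] = "".join(seq)
    return sequences


def _draw_abundance(rng: np.random.Generator, k: int, config: ScenarioConfig) -> np.ndarray:
    """Relative abundances for k OTUs under the configured abundance model."""
    if k == 0:
        return np.zeros(0)
    if config.abundance_model == "lognormal":
        x = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=k)
    else:  # log-series approximated by exponentially tilted geometric ranks
        ranks = np.arange(1, k + 1)
        x = rng.permutation(1.0 / ranks * np.exp(-0.05 * ranks))
    return x / x.sum()


def _assign_membership(
    config: ScenarioConfig, rng: np.random.Generator
) -> Tuple[np.ndarray, List[str]]:
    """Boolean OTU x group membership satisfying the sharing fractions.

    The first round(frac_ubiquitous*P) OTUs occupy every group, the next
    round(frac_unique*P) exactly one (round-robin), and the remainder a
    random subset of 2..G-1 groups.
    """
    groups = config.groups
    G = len(groups)
    P = config.otu_pool_size
    n_ub = int(np.floor(config.frac_ubiquitous * P + 0.5))
    n_un = int(np.floor(config.frac_unique * P + 0.5))
    n_shared = P - n_ub - n_un
    if n_shared > 0 and G < 3:
        raise ConfigurationError(
            "shared (non-ubiquitous, non-unique) OTUs need at least 3 groups"
        )
    member = np.zeros((P, G), dtype=bool)
    member[:n_ub, :] = True
    for i in range(n_un):
        member[n_ub + i, i % G] = True
    for i in range(n_shared):
        size = int(rng.integers(2, G))  # 2..G-1 inclusive
        cols = rng.choice(G, size=size, replace=False)
        member[n_ub + n_un + i, cols] = True
    return member, groups


def generate_scenario(config: ScenarioConfig) -> TransectScenario:
    """Generate a full ground-truth transect scenario.

    Deterministic for a fixed config (all randomness flows from
    ``config.seed`` through a fixed ordering of sub-draws). The succession
    group's per-layer community is a distance-weighted mixture of a base and
    a replacement community; all other layers are homogeneous along the path
    up to multiplicative peak-height noise.
    """
    rng = np.random.default_rng(config.seed)
    seq_seed, member_seed, comm_seed, env_seed, noise_seed = rng.integers(
        0, 2**31 - 1, size=5
    )

    otu_sequences = generate_otu_sequences(
        config.otu_pool_size,
        length=config.amplicon_length,
        trf_range=config.trf_range,
        seed=int(seq_seed),
        fwd_primer=config.fwd_primer,
        rev_primer=config.rev_primer,
    )
    otu_ids = list(otu_sequences)

    member, groups = _assign_membership(config, np.random.default_rng(int(member_seed)))
    P, G = member.shape
    n_ub = int(np.floor(config.frac_ubiquitous * P + 0.5))

    # succession split: the succession group's members are partitioned into a
    # base set (includes all ubiquitous members) and a replacement set
    crng = np.random.default_rng(int(comm_seed))
    succession_on = (
        config.succession_rate > 0 and config.succession_layer in groups
    )
    base_mask: Dict[str, np.ndarray] = {}
    alt_mask: Dict[str, np.ndarray] = {}
    for g_idx, g in enumerate(groups):
        members_g = np.where(member[:, g_idx])[0]
        if succession_on and g == config.succession_layer:
            movable = members_g[members_g >= n_ub]
            if len(movable) < 2:
                raise ConfigurationError(
                    "succession group needs at least 2 non-ubiquitous members"
                )
            k = len(movable) // 2
            alt_members = crng.choice(movable, size=k, replace=False)
            alt = np.zeros(P, dtype=bool)
            alt[alt_members] = True
            base = np.zeros(P, dtype=bool)
            base[members_g] = True
            base[alt_members] = False
        else:
            base = np.zeros(P, dtype=bool)
            base[members_g] = True
            alt = np.zeros(P, dtype=bool)
        base_mask[g] = base
        alt_mask[g] = alt

    base_communities: Dict[str, np.ndarray] = {}
    alt_communities: Dict[str, np.ndarray] = {}
    for layer in config.layers:
        g = config.layer_groups[layer]
        vec = np.zeros(P)
        idx = np.where(base_mask[g])[0]
        vec[idx] = _draw_abundance(crng, len(idx), config)
        base_communities[layer] = vec
        avec = np.zeros(P)
        aidx = np.where(alt_mask[g])[0]
        if len(aidx):
            avec[aidx] = _draw_abundance(crng, len(aidx), config)
        alt_communities[layer] = avec

    # layout: transect stations from the western entrance, off-path stations
    # continuing past the eastern exit at the transect spacing
    n_t, n_o = config.n_stations_transect, config.n_stations_offpath
    spacing = config.transect_length_km / (n_t - 1)
    stations = list(range(1, n_t + n_o + 1))
    distances = [spacing * i for i in range(n_t)] + [
        config.transect_length_km + spacing * (i + 1) for i in range(n_o)
    ]
    regions = ["transect"] * n_t + ["offpath"] * n_o
    layout = pd.DataFrame(
        {"station": stations, "along_path_km": distances, "region": regions}
    )

    L = len(config.layers)
    abundance = np.zeros((len(stations), L, P))
    nrng = np.random.default_rng(int(noise_seed))
    sigma = np.sqrt(np.log1p(config.noise_cv**2)) if config.noise_cv > 0 else 0.0
    for s, dist in enumerate(distances):
        for l, layer in enumerate(config.layers):
            g = config.layer_groups[layer]
            if succession_on and g == config.succession_layer:
                f = min(1.0, config.succession_rate * dist)
                vec = (1 - f) * base_communities[layer] + f * alt_communities[layer]
            else:
                vec = base_communities[layer].copy()
            if sigma > 0:
                noise = nrng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=P)
                vec = vec * noise
            total = vec.sum()
            abundance[s, l] = vec / total if total > 0 else vec

    # metadata: uniform draws inside each layer's environmental envelope,
    # plus depth-attenuated abundance/activity fields
    erng = np.random.default_rng(int(env_seed))
    records = []
    for s, st in enumerate(stations):
        for layer in config.layers:
            env = LAYER_ENVELOPES.get(layer)
            if env is None:
                raise ConfigurationError(f"no environmental envelope for {layer!r}")
            draws = {k: float(erng.uniform(lo, hi)) for k, (lo, hi) in env.items()}
            depth = draws.pop("depth_m")
            pa = 5e5 * np.exp(-depth / 900.0) * float(erng.lognormal(0, 0.2))
            leu = 3.8 * np.exp(-depth / 650.0) * float(erng.lognormal(0, 0.3))
            records.append(
                SampleMetadata(
                    sample_id=f"St{st:02d}_{layer}",
                    station=st,
                    layer=layer,
                    group=config.layer_groups[layer],
                    region=regions[s],
                    depth_m=depth,
                    along_path_km=distances[s],
                    prokaryotic_abundance=pa,
                    leucine_incorporation=leu,
                    **draws,
                )
            )
    metadata = pd.DataFrame([r.__dict__ for r in records])

    flags = []
    for i in range(P):
        k = member[i].sum()
        flag = "ubiquitous" if k == G else ("unique" if k == 1 else "shared")
        flags.append(flag)
    membership = pd.DataFrame(
        {
            "otu_id": otu_ids,
            "flag": flags,
            "groups": [
                ";".join(g for g, m in zip(groups, member[i]) if m)
                for i in range(P)
            ],
        }
    )

    return TransectScenario(
        config=config,
        otu_ids=otu_ids,
        otu_sequences=otu_sequences,
        abundance=abundance,
        stations=stations,
        layers=list(config.layers),
        metadata=metadata,
        layout=layout,
        membership=membership,
        base_communities=base_communities,
        alt_communities=alt_communities,
    )


def sample_clone_library(
    abundance_vector: Sequence[float],
    n_clones: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Multinomial clone-library draw from a relative-abundance vector."""
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    p = np.asarray(abundance_vector, dtype=float)
    if p.min() < 0 or not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("abundances must be non-negative and sum to 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    return rng.multinomial(n_clones, p / p.sum())
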