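"""End-to-end pipeline wiring: simulate -> digest -> fingerprint ->
resemble -> cluster -> relate -> diversity -> succession.

Each stage writes its outputs into a stage-named subdirectory of the run
directory together with a sidecar metadata record; a run summary and a log
of versions, seeds and parameters complete the run. Two runs with the same
config produce byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from pathlib import Path
from typing import Dict, Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, dump_config
from .diversity import diversity_summary, incidence_summary
from .io import (
    write_fasta,
    write_fingerprint_matrix,
    write_newick,
    write_peak_table,
    write_resemblance_matrix,
)
from .simulate import ENV_VARIABLES, TransectScenario, generate_scenario
from .structure import bray_curtis_matrix, env_distance_matrix, relate, upgma
from .succession import run_succession_analysis
from .trflp import (
    TerminalFragment,
    bin_and_standardize,
    digest_amplicons,
    find_amplicon,
    profile_sample,
)

__all__ = ["run_pipeline"]

log = logging.getLogger("trflpkit")


def _sidecar(path: Path, params: Dict) -> None:
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(params, indent=2, sort_keys=True, default=str) + "\n"
    )


def scenario_fragments(
    scenario: TransectScenario,
    site: str,
    cut_offset: int,
    channel: str = "forward",
) -> Dict[str, TerminalFragment]:
    """Digest every OTU sequence of a scenario on one channel."""
    cfg = scenario.config
    frags = {}
    for otu_id, seq in scenario.otu_sequences.items():
        amp = find_amplicon(seq, cfg.fwd_primer, cfg.rev_primer, otu_id=otu_id)
        from .trflp import terminal_fragment

        frags[otu_id] = terminal_fragment(
            amp, site=site, cut_offset=cut_offset, channel=channel
        )
    return frags


def scenario_profiles(
    scenario: TransectScenario,
    fragments: Dict[str, TerminalFragment],
    scale: float = 1000.0,
    noise_cv: float = 0.0,
    seed: Optional[int] = None,
):
    """One peak profile per scenario sample, in metadata order."""
    rng = np.random.default_rng(seed)
    profiles = []
    for _, row in scenario.metadata.iterrows():
        community = scenario.community(row["station"], row["layer"])
        profiles.append(
            profile_sample(
                community,
                fragments,
                sample_id=row["sample_id"],
                scale=scale,
                noise_cv=noise_cv,
                rng=rng,
            )
        )
    return profiles


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full chain and return the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        level=logging.DEBUG if config.verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )
    dump_config(config, outdir / "config.yaml")
    (outdir / "run.log").write_text(
        json.dumps(
            {
                "trflpkit": __version__,
                "python": platform.python_version(),
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "seed": config.seed,
            },
            indent=2,
        )
        + "\n"
    )
    rng = np.random.default_rng(config.seed)
    summary: Dict = {"stages": {}}

    def stage_dir(name: str) -> Path:
        d = outdir / name
        d.mkdir(exist_ok=True)
        return d

    try:
        # -- simulate ------------------------------------------------------
        d = stage_dir("simulate")
        scenario = generate_scenario(
            dataclasses.replace(config.scenario, seed=int(rng.integers(0, 2**31 - 1)))
        )
        write_fasta(scenario.otu_sequences, d / "otus.fasta")
        scenario.abundance_long().to_csv(
            d / "abundance.csv", index=False, float_format="%.12g"
        )
        scenario.metadata.to_csv(d / "metadata.csv", index=False, float_format="%.12g")
        scenario.membership.to_csv(d / "membership.csv", index=False)
        _sidecar(d / "abundance.csv", dataclasses.asdict(config.scenario))
        summary["stages"]["simulate"] = {
            "n_otus": len(scenario.otu_ids),
            "n_samples": len(scenario.metadata),
        }

        # -- digest --------------------------------------------------------
        d = stage_dir("digest")
        amps = [
            find_amplicon(seq, config.scenario.fwd_primer,
                          config.scenario.rev_primer, otu_id=otu)
            for otu, seq in scenario.otu_sequences.items()
        ]
        frag_table = digest_amplicons(
            amps, site=config.enzyme_site, cut_offset=config.cut_offset
        )
        frag_table.to_csv(d / "fragments.csv", index=False)
        _sidecar(d / "fragments.csv",
                 {"site": config.enzyme_site, "cut_offset": config.cut_offset})
        fragments = scenario_fragments(
            scenario, config.enzyme_site, config.cut_offset, config.channel
        )
        summary["stages"]["digest"] = {
            "n_fragments": len(frag_table),
            "n_uncut": int((~frag_table["cut"]).sum()),
        }

        # -- fingerprint ---------------------------------------------------
        d = stage_dir("fingerprint")
        profiles = scenario_profiles(
            scenario,
            fragments,
            scale=config.peak_scale,
            noise_cv=config.scenario.noise_cv,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        write_peak_table(profiles, d / "peaks.csv")
        fingerprints = bin_and_standardize(
            profiles,
            bin_width=config.bin_width,
            size_min=config.size_min,
            size_max=config.size_max,
            rel_threshold=config.rel_threshold,
        )
        write_fingerprint_matrix(fingerprints, d / "fingerprints.csv")
        _sidecar(d / "fingerprints.csv", {
            "bin_width": config.bin_width, "size_min": config.size_min,
            "size_max": config.size_max, "rel_threshold": config.rel_threshold,
        })
        summary["stages"]["fingerprint"] = {
            "n_bins": len(fingerprints.bin_centers)
        }

        # -- resemble ------------------------------------------------------
        d = stage_dir("resemble")
        community_res = bray_curtis_matrix(fingerprints)
        write_resemblance_matrix(community_res, d / "bray_curtis.csv")
        env_res = env_distance_matrix(scenario.metadata, ENV_VARIABLES)
        write_resemblance_matrix(env_res, d / "env_distance.csv")
        bio_res = env_distance_matrix(
            scenario.metadata,
            ["prokaryotic_abundance", "leucine_incorporation"],
            log_transform=["prokaryotic_abundance", "leucine_incorporation"],
        )
        write_resemblance_matrix(bio_res, d / "bio_distance.csv")

        # -- cluster -------------------------------------------------------
        d = stage_dir("cluster")
        dendro = upgma(community_res)
        write_newick(dendro, d / "dendrogram.nwk")

        # -- relate --------------------------------------------------------
        d = stage_dir("relate")
        relate_rows = []
        for name, other in (("env", env_res), ("bio", bio_res)):
            mr = relate(
                community_res.as_distance(),
                other,
                n_perm=config.n_perm,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            relate_rows.append(
                {"comparison": f"{name}_vs_community", "rho": mr.rho,
                 "p": mr.p, "n_perm": mr.n_perm}
            )
        relate_df = pd.DataFrame(relate_rows)
        relate_df.to_csv(d / "relate.csv", index=False, float_format="%.12g")
        summary["stages"]["relate"] = relate_rows

        # -- diversity -----------------------------------------------------
        d = stage_dir("diversity")
        div_rows = []
        fp = fingerprints.to_frame()
        for sample_id, row in fp.iterrows():
            ds = diversity_summary(row.to_numpy())
            div_rows.append(
                {"sample": sample_id, "s_obs": ds.s_obs, "shannon": ds.shannon}
            )
        pd.DataFrame(div_rows).to_csv(
            d / "diversity.csv", index=False, float_format="%.12g"
        )
        groups = dict(zip(scenario.metadata["sample_id"], scenario.metadata["group"]))
        inc = incidence_summary(fp, groups)
        summary["stages"]["incidence"] = {
            "n_total": inc.n_total,
            "n_ubiquitous": inc.n_ubiquitous,
            "pct_ubiquitous": inc.pct_ubiquitous,
            "n_unique": inc.n_unique,
            "pct_unique": inc.pct_unique,
            "pct_prevalent": inc.pct_prevalent,
        }

        # -- succession ----------------------------------------------------
        d = stage_dir("succession")
        layout = scenario.metadata[
            ["sample_id", "station", "layer", "group", "along_path_km", "region"]
        ]
        results = run_succession_analysis(
            fingerprints,
            layout,
            regions=("transect", "offpath"),
            n_boot=config.n_boot,
            n_null=config.n_null,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        results.to_csv(d / "succession.csv", index=False, float_format="%.12g")
        summary["stages"]["succession"] = results.to_dict(orient="records")
    except Exception as e:
        raise RuntimeError(f"pipeline stage failed: {e}") from e

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=float) + "\n"
    )
    log.info("run complete: %s", outdir)
    return outdir
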