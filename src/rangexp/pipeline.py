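"""End-to-end run orchestration: filter -> select -> polarize -> psi ->
origin scan -> IBD test -> PCoA -> heterozygosity, plus the analysis matrix
of setting combinations."""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import genotypes, origin, pcoa, polarization, selection
from .directionality import compute_psi_matrix
from .genotypes import read_genotype_table, read_sample_info, write_outputs
from .selection import SelectionConfig

logger = logging.getLogger("rangexp")


@dataclass
class RunConfig:
    genotypes_path: str = ""
    genotypes_format: str = "tsv"
    sample_info_path: str = ""
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    outgroup_taxon: str | None = None
    m: int = 2                      # psi projection size (chromosomes)
    bootstrap: int = 0              # psi bootstrap replicates (0 = off)
    spacing_deg: float = 0.25
    padding_fraction: float = 0.5
    n_perm: int = 199
    pcoa_axes: int = 2
    seed: int = 0
    out_dir: str = "rangexp_out"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sel = d.pop("selection", {})
        if isinstance(sel, dict):
            sel = SelectionConfig(**sel)
        return cls(selection=sel, **d)


def run_pipeline(cfg: RunConfig, table=None, info=None, write: bool = True) -> dict:
    """Execute the full analysis; returns the JSON-able run summary.

    ``table``/``info`` may be passed directly (e.g. from the simulator);
    otherwise they are read from the configured paths.
    """
    stage = "load"
    try:
        if table is None:
            table = read_genotype_table(cfg.genotypes_path, cfg.genotypes_format)
        if info is None:
            info = read_sample_info(cfg.sample_info_path)

        stage = "selection"
        sel_table, sel_info = selection.apply_selection(table, info, cfg.selection)

        stage = "polarization"
        counts = polarization.polarize_table(sel_table, sel_info, cfg.outgroup_taxon)

        stage = "psi"
        psi = compute_psi_matrix(counts, m=cfg.m, B=cfg.bootstrap, seed=cfg.seed)

        stage = "origin"
        grid = origin.make_grid(sel_info, cfg.spacing_deg, cfg.padding_fraction)
        surface = origin.origin_scan(psi, sel_info, grid)
        surface.pvalue = origin.test_expansion_vs_ibd(
            psi, sel_info, grid, n_perm=cfg.n_perm, seed=cfg.seed)

        stage = "pcoa"
        ingroup_ids = [r.sample_id for r in sel_info if r.role == "ingroup"]
        embedding = None
        if len(ingroup_ids) >= 3:
            embedding = pcoa.pcoa_from_table(sel_table.subset_samples(ingroup_ids),
                                             axes=cfg.pcoa_axes)
        het = pcoa.population_heterozygosity(sel_table, sel_info)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    summary = {
        "config": cfg.to_dict(),
        "n_sites_input": table.n_sites,
        "n_sites_analyzed": counts.n_sites,
        "n_populations": len(psi.populations),
        "origin": surface.summary(),
        "heterozygosity": het,
        "seed": cfg.seed,
    }
    if write:
        manifest = write_outputs(psi, surface, embedding, cfg.out_dir)
        cfg_path = os.path.join(cfg.out_dir, "resolved_config.json")
        with open(cfg_path, "w") as fh:
            json.dump(cfg.to_dict(), fh, indent=2, sort_keys=True)
        manifest.append(cfg_path)
        summary["manifest"] = manifest
        with open(os.path.join(cfg.out_dir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    return summary


def run_matrix(base_cfg: RunConfig, axes: dict[str, list], table=None, info=None,
               write: bool = False) -> pd.DataFrame:
    """Cartesian product of option values, one pipeline run per cell.

    ``axes`` maps dotted option names (e.g. ``selection.snp_choice_mode``,
    ``outgroup_taxon``) to lists of values.  Failing cells are recorded with
    their error message and the remaining cells continue.
    """
    names = list(axes)
    combos = list(itertools.product(*(axes[n] for n in names))) if names else [()]
    rows = []
    for combo in combos:
        cfg = RunConfig.from_dict(base_cfg.to_dict())
        for name, value in zip(names, combo):
            if name.startswith("selection."):
                setattr(cfg.selection, name.split(".", 1)[1], value)
            else:
                setattr(cfg, name, value)
        if write:
            tag = "_".join(f"{n.split('.')[-1]}-{v}" for n, v in zip(names, combo))
            cfg.out_dir = os.path.join(base_cfg.out_dir, tag or "base")
        row = {n: v for n, v in zip(names, combo)}
        try:
            summary = run_pipeline(cfg, table=table, info=info, write=write)
            row.update({
                "origin_lat": summary["origin"]["best_lat"],
                "origin_lon": summary["origin"]["best_lon"],
                "slope_per_km": summary["origin"]["slope_per_km"],
                "r2": summary["origin"]["r2"],
                "pvalue": summary["origin"]["pvalue"],
                "boundary_flag": summary["origin"]["boundary_flag"],
                "error": "",
            })
        except Exception as exc:
            logger.error("matrix cell %s failed: %s", row, exc)
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)
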