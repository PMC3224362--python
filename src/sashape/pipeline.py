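"""End-to-end orchestration: encode → compartments → statistics → deformation.

All tunable thresholds (probe radius, burial/interface cut-offs, equality
tolerance, test level, Bonferroni sidedness) live in :class:`PipelineConfig`
rather than being hard-coded; defaults are the standard choices (1.4 Å water
probe, 5% burial, 1-point interface change, α = 0.05).
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .deformation import (delta_p, deformation_proportions, exposure_difference,
                          pair_chains, transition_counts)
from .encoder import assign_letters
from .io import ComplexStructure, read_pdb, write_structural_fasta
from .model import AlphabetModel, default_model, load_model
from .sasa import accessibility_contexts, assign_compartment
from .stats import count_letters, kld_table, zscore_table

__all__ = ["PipelineConfig", "run_pipeline", "encode_structure",
           "compartment_records", "compartment_table"]


@dataclass
class PipelineConfig:
    model_path: str | None = None
    probe: float = 1.4
    n_points: int = 960
    interface_threshold: float = 1.0     # points of accessibility change
    burial_threshold: float = 5.0        # percent
    equality_tolerance: float = 0.05     # points
    alpha: float = 0.05
    bonferroni_sided: str = "two"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.probe, self.interface_threshold, self.burial_threshold,
               self.equality_tolerance) < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def load_model(self) -> AlphabetModel:
        if self.model_path:
            return load_model(self.model_path)
        return default_model()


def _log(stage: str, t0: float) -> None:
    print(f"[sashape] {stage}: {time.perf_counter() - t0:.2f}s", file=sys.stderr)


def encode_structure(structure: ComplexStructure, model: AlphabetModel,
                     chain_ids=None) -> list:
    chain_ids = chain_ids or list(structure.chains)
    return [assign_letters(structure.chains[cid], model,
                           name=f"{structure.name}_{cid}")
            for cid in chain_ids]


def compartment_records(structure: ComplexStructure, config: PipelineConfig,
                        chain_ids=None, reference=None) -> list:
    chain_ids = chain_ids or list(structure.chains)
    records = []
    for cid in chain_ids:
        recs = accessibility_contexts(structure, cid, reference=reference,
                                      probe=config.probe,
                                      n_points=config.n_points)
        for r in recs:
            if r.has_reference:
                r.compartment = assign_compartment(
                    r, burial_threshold=config.burial_threshold,
                    interface_delta=config.interface_threshold,
                    tol=config.equality_tolerance)
        records.extend(recs)
    return records


def compartment_table(records) -> pd.DataFrame:
    return pd.DataFrame([{
        "chain": r.residue.chain_id,
        "resnum": r.residue.residue_number,
        "icode": r.residue.insertion_code.strip(),
        "aa": r.aa,
        "a_chain": round(r.a_chain, 2),
        "a_interf": round(r.a_interf, 2),
        "a_complex": round(r.a_complex, 2),
        "compartment": r.compartment,
    } for r in records])


def run_pipeline(config: PipelineConfig, pdb_path, pair: tuple[str, str],
                 outdir, unbound_paths: dict[str, str] | None = None) -> dict:
    """Run the full analysis on one complex; optionally add the deformation
    stage when unbound structures are supplied per bound chain id.

    Writes structural sequences, the compartment table, count and statistics
    tables, deformation matrices (if applicable) and a run manifest; returns
    the paths of everything written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}
    t0 = time.perf_counter()
    try:
        model = config.load_model()
    except Exception as exc:
        raise RuntimeError(f"[model] {exc}") from exc
    try:
        structure = read_pdb(pdb_path, pair_of_interest=pair)
        _log("read", t0)
    except Exception as exc:
        raise RuntimeError(f"[read] {exc}") from exc

    t = time.perf_counter()
    sequences = encode_structure(structure, model, chain_ids=list(pair))
    fasta = outdir / "structural_sequences.fasta"
    write_structural_fasta(sequences, fasta)
    written["sequences"] = str(fasta)
    _log("encode", t)

    t = time.perf_counter()
    records = compartment_records(structure, config, chain_ids=list(pair))
    comp = outdir / "compartments.tsv"
    compartment_table(records).to_csv(comp, sep="\t", index=False)
    written["compartments"] = str(comp)
    _log("compartments", t)

    t = time.perf_counter()
    table = count_letters(sequences, records)
    counts_path = outdir / "letter_counts.tsv"
    table.counts.to_csv(counts_path, sep="\t")
    written["counts"] = str(counts_path)
    kld_path = outdir / "kld.tsv"
    kld_table(table, alpha=config.alpha).to_csv(kld_path, sep="\t")
    written["kld"] = str(kld_path)
    z_path = outdir / "zscores.tsv"
    zscore_table(table, alpha=config.alpha,
                 sided=config.bonferroni_sided).to_csv(z_path, sep="\t", index=False)
    written["zscores"] = str(z_path)
    _log("stats", t)

    if unbound_paths:
        t = time.perf_counter()
        long_rows = []
        for cid, upath in unbound_paths.items():
            unbound = read_pdb(upath)
            uchain = next(iter(unbound.chains.values()))
            pmap = pair_chains(uchain, structure.chains[cid])
            useq = assign_letters(uchain, model, name=f"unbound_{cid}")
            bseq = next(s for s in sequences if s.chain.chain_id == cid)
            recs = [r for r in records if r.residue.chain_id == cid]
            c = transition_counts(pmap, useq, bseq, recs)
            p_i = deformation_proportions(c["interface"])
            p_s = deformation_proportions(c["surface"])
            dp, _missing = delta_p(p_i, p_s)
            for cp, mat in c.items():
                stacked = mat.stack()
                for (sl1, sl2), v in stacked[stacked > 0].items():
                    long_rows.append({"chain": cid, "matrix": f"C_{cp}",
                                      "sl1": sl1, "sl2": sl2, "value": int(v)})
            for tag, mat in (("P_interf", p_i), ("P_surf", p_s), ("deltaP", dp)):
                stacked = mat.stack(future_stack=True).dropna()
                for (sl1, sl2), v in stacked[stacked != 0].items():
                    long_rows.append({"chain": cid, "matrix": tag,
                                      "sl1": sl1, "sl2": sl2, "value": float(v)})
        deform_path = outdir / "deformation.tsv"
        pd.DataFrame(long_rows).to_csv(deform_path, sep="\t", index=False)
        written["deformation"] = str(deform_path)
        _log("deform", t)

    manifest = {
        "config": asdict(config),
        "inputs": {"pdb": str(pdb_path), "pair": list(pair),
                   "unbound": unbound_paths or {}},
        "outputs": written,
        "versions": {"sashape": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    written["manifest"] = str(manifest_path)
    _log("total", t0)
    return written
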