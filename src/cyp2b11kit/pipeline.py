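"""End-to-end orchestration from a YAML scenario file.

A scenario names a seed, an output directory, and the stages to run; every
stage writes its outputs once into the output directory, and a JSON
manifest records the package version, seed, stage list, and SHA-256
digests of every file written, so a rerun with the same scenario is
bit-identical for the deterministic stages (the manifest timestamp aside).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__, datasets, popgen
from .ase import corrected_ratio_profile, detect_imbalance
from .motifs import motif_diff, scan_motif
from .phenotyping import DOG_LIVER_CYP_ABUNDANCE, extrapolate_to_microsomes
from .simulate import (
    ActivitySimParams,
    AseSimParams,
    BreedSpec,
    gen_activity_panel,
    gen_allelic_counts,
    gen_breed_panel,
    gen_utr_sequence,
)
from .variants import write_fasta, write_genotypes

log = logging.getLogger("cyp2b11kit")

STAGES = ("simulate", "freq", "phase", "ld", "diplofreq", "ase", "phenotype", "polya")


@dataclass
class Scenario:
    seed: int
    out_dir: Path
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    params: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Scenario":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        stages = raw.get("stages", list(STAGES))
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        return cls(
            seed=int(raw.get("seed", 0)),
            out_dir=Path(raw.get("out_dir", "pipeline_out")),
            stages=stages,
            params=raw.get("params", {}),
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(scenario: Scenario) -> dict:
    """Run the requested stages; returns the manifest dictionary.

    A stage failure propagates with the stage name attached; outputs of
    earlier stages are retained on disk.
    """
    out = Path(scenario.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    variants = datasets.load_variant_table()
    hapset = datasets.load_discovery_haplotypes()
    state: dict[str, Any] = {}

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        written.append(path)
        log.info("wrote %s", path)

    for stage in scenario.stages:
        log.info("stage %s", stage)
        try:
            if stage == "simulate":
                specs = [
                    BreedSpec(name=s["name"], group=s["group"], n_dogs=int(s["n_dogs"]),
                              haplotype_freqs=s["haplotype_freqs"])
                    for s in scenario.params.get(
                        "breeds",
                        [{"name": "Greyhound", "group": "sighthound", "n_dogs": 100,
                          "haplotype_freqs": datasets.greyhound_breed_spec_freqs()}],
                    )
                ]
                panel, truth = gen_breed_panel(specs, hapset, variants, scenario.seed)
                state["panel"] = panel
                emit("genotypes.tsv", lambda p: write_genotypes(panel, variants, p))
                emit("diplotype_truth.tsv", lambda p: truth.to_csv(p, sep="\t", index=False))
            elif stage == "freq":
                panel = state.get("panel")
                if panel is None:
                    raise RuntimeError("freq stage needs the simulate stage (or a loaded panel)")
                freqs = popgen.allele_frequencies(panel, variants)
                df = pd.DataFrame(
                    [{"site_id": s, "k": f.k, "n": f.n, "p_hat": f.p_hat,
                      "ci_low": f.ci_low, "ci_high": f.ci_high} for s, f in freqs.items()]
                )
                emit("allele_frequencies.tsv", lambda p: df.to_csv(p, sep="\t", index=False))
            elif stage == "phase":
                panel = state.get("panel")
                if panel is None:
                    raise RuntimeError("phase stage needs the simulate stage")
                res = popgen.em_phase(panel, variants)
                state["phasing"] = res
                rows = [
                    {"label": lab, "alleles": "|".join(res.haplotypes.haplotypes[lab]),
                     "em_frequency": res.haplotypes.frequencies["em"][lab]}
                    for lab in res.haplotypes.haplotypes
                ]
                emit("em_haplotypes.tsv",
                     lambda p: pd.DataFrame(rows).to_csv(p, sep="\t", index=False))
                dip = pd.DataFrame(
                    [{"dog_id": d, "hap_a": a, "hap_b": b} for d, (a, b) in res.diplotypes.items()]
                )
                emit("em_diplotypes.tsv", lambda p: dip.to_csv(p, sep="\t", index=False))
            elif stage == "ld":
                pools = scenario.params.get("ld_pools", ["greyhound", "other_breeds"])
                for pool in pools:
                    mat = popgen.ld_matrix(hapset, pool, variants)
                    rows = [
                        {"site_i": a, "site_j": b, "D": r.D, "r2": r.r2,
                         "r2_percent": r.displayed_r2_percent}
                        for (a, b), r in mat.items()
                    ]
                    emit(f"ld_{pool}.tsv",
                         lambda p, rows=rows: pd.DataFrame(rows).to_csv(p, sep="\t", index=False))
            elif stage == "diplofreq":
                rows = []
                for pop, dc in datasets.load_diplotype_counts().items():
                    for lab, d in popgen.haplotype_freqs_from_diplotypes(dc).items():
                        rows.append({"population": pop, "haplotype": lab,
                                     "frequency": d["frequency"], "percent": d["percent"]})
                emit("diplotype_haplotype_freqs.tsv",
                     lambda p: pd.DataFrame(rows).to_csv(p, sep="\t", index=False))
            elif stage == "ase":
                pr = scenario.params.get("ase", {})
                params = AseSimParams(
                    true_ratio=float(pr.get("true_ratio", 0.1)),
                    mapping_bias=float(pr.get("mapping_bias", 0.8)),
                    depth_rna=int(pr.get("depth_rna", 500)),
                    depth_dna=int(pr.get("depth_dna", 500)),
                    n_samples=int(pr.get("n_samples", 6)),
                    seed=scenario.seed,
                )
                rna, dna = gen_allelic_counts(params)
                rna["breed"], rna["diplotype"] = "sim", "H1/H2"
                dna["diplotype"] = "H1/H2"
                prof = corrected_ratio_profile(rna, dna)
                prof = detect_imbalance(prof)
                emit("ase_profile.tsv", lambda p: prof.to_csv(p, sep="\t", index=False))
            elif stage == "phenotype":
                pr = scenario.params.get("phenotype", {})
                rates = pr.get("specific_rates", {"CYP2B11": 1.0, "CYP3A12": 1.0})
                table = extrapolate_to_microsomes(rates, DOG_LIVER_CYP_ABUNDANCE,
                                                  pooled_rate=pr.get("pooled_rate"))
                emit("extrapolation.tsv", lambda p: table.to_csv(p, sep="\t", index=False))
                sim = pr.get("simulate_panel")
                if sim:
                    params = ActivitySimParams(
                        abundances=sim.get("abundances", DOG_LIVER_CYP_ABUNDANCE),
                        intrinsic_rates=sim["intrinsic_rates"],
                        noise_cv=float(sim.get("noise_cv", 0.3)),
                        n_livers=int(sim.get("n_livers", 15)),
                        seed=scenario.seed,
                        readout_cv=float(sim.get("readout_cv", 0.0)),
                    )
                    act, prot = gen_activity_panel(params)
                    emit("liver_activity.tsv", lambda p: act.to_csv(p, sep="\t", index=False))
                    emit("liver_protein.tsv", lambda p: prot.to_csv(p, sep="\t", index=False))
            elif stage == "polya":
                pr = scenario.params.get("polya", {})
                utr3 = [v for v in variants if v.region == "utr3"]
                length = int(pr.get("length", 2625))
                positions = list(pr.get("motif_positions", [1715, 2582]))
                ref, alt = gen_utr_sequence(length, positions, utr3, scenario.seed)
                emit("utr_synthetic.fasta",
                     lambda p: write_fasta({"utr_ref_synthetic": ref, "utr_var_synthetic": alt}, p))
                hits = scan_motif(ref)
                created, destroyed = motif_diff(ref, utr3)
                report = {
                    "hits": [h.cdna_start for h in hits],
                    "created": [h.cdna_start for h in created],
                    "destroyed": [h.cdna_start for h in destroyed],
                }
                emit("polya_report.json", lambda p: p.write_text(json.dumps(report, indent=2)))
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package": "cyp2b11kit",
        "version": __version__,
        "seed": scenario.seed,
        "stages": list(scenario.stages),
        "outputs": {p.name: _sha256(p) for p in written},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
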