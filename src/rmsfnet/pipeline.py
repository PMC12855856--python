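"""End-to-end pipeline orchestration with a flat JSON config.

Stage order mirrors the analysis workflow: ingest paired RMSF tables ->
coupling statistics -> network scan and selection -> topology -> shortest
paths from the focal residue -> consensus communities, plus the paired
Wilcoxon and immunogenicity screens.  Every stage's randomness derives from
a master seed through named spawns, so changing one stage's iteration count
never perturbs another stage's stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import corrstats, io_formats, network, synthetic, topology
from .residues import ResidueKey, SequentialNumbering, parse_residue_key

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat, JSON-serializable pipeline configuration."""

    manifest: str = ""  # TSV: trajectory_id, copy_id, condition, provenance, path
    structure: str = ""  # PDB with Cα coordinates
    output_dir: str = "rmsfnet_out"
    n_heavy: int = 180
    n_peptide: int = 9
    alpha: float = 0.05
    rho_min: float = 0.5
    null_resamples: int = 100_000
    screen_resamples: int = 100_000
    screen_top_k: int = 5
    louvain_iterations: int = 10_000
    louvain_resolution: float = 1.0
    scan_exponents: list[float] = field(default_factory=lambda: [0.0, 0.5, 1.0, 2.0])
    scan_thresholds: list[float] = field(default_factory=lambda: list(range(6, 54, 2)))
    chosen_exponent: float | None = None  # None -> use scan selection
    chosen_threshold: float | None = None
    focal_residue: str = "p3"
    wilcoxon_residues: list[str] = field(default_factory=lambda: ["p3", "p4", "p6"])
    wilcoxon_alternatives: list[str] = field(default_factory=lambda: ["less", "greater", "greater"])
    seed: int = 0
    stop_after: str = ""  # '', 'correlate', 'network', 'topology'

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def stage_seed(self, stage: str) -> int:
        """Independent per-stage seed derived from the master seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def load_inputs(config: RunConfig) -> tuple[io_formats.RmsfDataset, io_formats.CaCoordinates]:
    manifest = pd.read_csv(config.manifest, sep="\t")
    numbering = SequentialNumbering(config.n_heavy, config.n_peptide)
    base = Path(config.manifest).parent
    profiles = []
    for _, row in manifest.iterrows():
        path = Path(row["path"])
        if not path.is_absolute():
            path = base / path
        profile = io_formats.read_rmsf_xvg(
            path,
            trajectory_id=row["trajectory_id"],
            copy_id=row["copy_id"],
            condition=row["condition"],
            provenance=row.get("provenance", "crystal"),
            numbering=numbering,
        )
        if "p3_identity" in row and isinstance(row["p3_identity"], str):
            profile.identities[ResidueKey("peptide", 3)] = row["p3_identity"]
        profiles.append(profile)
    dataset = io_formats.harmonize_residues(profiles)
    selection = {
        "A": ("heavy", range(1, config.n_heavy + 1)),
        "C": ("peptide", range(1, config.n_peptide + 1)),
    }
    coords = io_formats.read_ca_coordinates(config.structure, selection=selection)
    return dataset, coords


def run_pipeline(
    config: RunConfig,
    dataset: io_formats.RmsfDataset | None = None,
    coords: io_formats.CaCoordinates | None = None,
) -> Path:
    """Execute the full workflow; returns the output directory.

    ``dataset``/``coords`` may be passed directly (e.g. from the synthetic
    generator); otherwise they are loaded per the config.  Any stage failure
    propagates after partial outputs are flushed, with the stage named.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        if dataset is None or coords is None:
            dataset, coords = load_inputs(config)
        labels = dataset.labels

        # --- correlation statistics -----------------------------------
        stage = "correlate"
        corr = corrstats.correlate(
            dataset,
            resamples=config.null_resamples,
            seed=config.stage_seed("null"),
            alpha=config.alpha,
            rho_min=config.rho_min,
        )
        names = [str(r) for r in corr.residues]
        for attr in ("rho", "p_raw", "p_adj"):
            pd.DataFrame(getattr(corr, attr), index=names, columns=names).to_csv(
                out / f"{attr}.csv"
            )
        corr.volcano_table(labels).to_csv(out / "volcano.csv", index=False)

        stage = "wilcoxon"
        wil_rows = []
        for res_text, alternative in zip(config.wilcoxon_residues, config.wilcoxon_alternatives):
            key = parse_residue_key(res_text)
            v, p = dataset.paired_values(key)
            # alternative refers to the P condition relative to V
            result = corrstats.wilcoxon_exact_paired(p, v, alternative=alternative)
            wil_rows.append(
                {
                    "residue": labels.get(key, res_text),
                    "alternative_P_vs_V": alternative,
                    "W": result.statistic,
                    "p_value": result.p_value,
                    "n_used": result.n_used,
                    "n_zero": result.n_zero,
                }
            )
        pd.DataFrame(wil_rows).to_csv(out / "wilcoxon.tsv", sep="\t", index=False)

        stage = "screen"
        screen = corrstats.immunogenicity_screen(
            dataset,
            resamples=config.screen_resamples,
            seed=config.stage_seed("screen"),
            top_k=config.screen_top_k,
        )
        screen.to_frame(labels).to_csv(out / "screen.tsv", sep="\t", index=False)

        stage = "cluster"
        keep = ~corr.degenerate
        kept_res = [r for r, k in zip(corr.residues, keep) if k]
        tree = corrstats.upgma_cluster(corr.rho[np.ix_(keep, keep)], kept_res)
        focal = parse_residue_key(config.focal_residue)
        partition, height = corrstats.cut_containing(tree, focal)
        (out / "upgma.json").write_text(
            json.dumps(
                {
                    "cut_height": height,
                    "clusters": [sorted(str(r) for r in c) for c in partition],
                },
                indent=2,
            )
        )
        if config.stop_after == "correlate":
            _write_provenance(config, out)
            return out

        # --- network construction -------------------------------------
        stage = "network"
        report = network.scan_parameters(
            corr,
            coords,
            n_grid=config.scan_exponents,
            t_grid=config.scan_thresholds,
            alpha=config.alpha,
            rho_min=config.rho_min,
        )
        report.table.to_csv(out / "scan.csv", index=False)
        if config.chosen_exponent is not None and config.chosen_threshold is not None:
            chosen_n, chosen_t = config.chosen_exponent, config.chosen_threshold
        else:
            selection = network.select_network(report)
            chosen_n, chosen_t = selection.exponent, selection.threshold
            if not selection.constraint_met:
                log.warning("no scanned network met the LCC constraint; using best effort")
        g = network.build_network(
            corr,
            coords,
            network.EdgeWeightParams(
                exponent=chosen_n, threshold=chosen_t,
                alpha=config.alpha, rho_min=config.rho_min,
            ),
            labels=labels,
        )
        io_formats.write_network(g, out / "network", fmt="edge_csv")
        io_formats.write_network(g, out / "network.graphml", fmt="graphml")
        if config.stop_after == "network":
            _write_provenance(config, out, chosen=(chosen_n, chosen_t))
            return out

        # --- topology --------------------------------------------------
        stage = "topology"
        metrics = topology.node_metrics(g)
        metrics.to_tsv(out / "node_metrics.tsv")

        stage = "paths"
        path_map = topology.paths_from(g, focal)
        path_map.to_frame(labels).to_csv(out / "paths_from_focal.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"source": str(a), "target": str(b)} for a, b in sorted(path_map.traversed_edges)]
        ).to_csv(out / "paths_from_focal_edges.tsv", sep="\t", index=False)
        if config.stop_after == "topology":
            _write_provenance(config, out, chosen=(chosen_n, chosen_t))
            return out

        stage = "communities"
        consensus = topology.louvain_consensus(
            g,
            focal=focal,
            iterations=config.louvain_iterations,
            seed=config.stage_seed("louvain"),
            resolution=config.louvain_resolution,
        )
        consensus.co_occurrence_frame(labels).to_csv(out / "co_occurrence.tsv", sep="\t", index=False)
        (out / "communities.json").write_text(
            json.dumps(
                {
                    "iterations": consensus.iterations,
                    "most_frequent_share": consensus.most_frequent_share,
                    "most_frequent_partition": [
                        sorted(str(r) for r in c) for c in consensus.most_frequent_partition
                    ],
                },
                indent=2,
            )
        )
        _write_provenance(config, out, chosen=(chosen_n, chosen_t))
        return out
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _write_provenance(config: RunConfig, out: Path, chosen=None) -> None:
    from . import __version__

    payload = dataclasses.asdict(config)
    config_hash = hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()
    (out / "provenance.json").write_text(
        json.dumps(
            {
                "package_version": __version__,
                "config": payload,
                "config_hash": config_hash,
                "chosen_network": chosen,
            },
            indent=2,
        )
    )


def write_synthetic_inputs(study: synthetic.SyntheticStudy, out_dir: str | Path) -> Path:
    """Write a synthetic study as exactly the on-disk inputs the analysis
    consumes: one .xvg per trajectory, a Cα PDB, a manifest TSV, and the
    ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = study.truth
    numbering = SequentialNumbering(spec.n_heavy, spec.n_peptide)
    ordered = numbering.keys()
    rows = []
    for profile in study.dataset.profiles:
        fname = f"rmsf_{profile.trajectory_id}.xvg"
        lines = [
            "@    title \"RMSF (synthetic)\"",
            "@    xaxis label \"Residue\"",
            "@    yaxis label \"(nm)\"",
        ]
        for i, key in enumerate(ordered, start=1):
            lines.append(f"{i:6d}  {profile.values[key]:.6f}")
        (out / fname).write_text("\n".join(lines) + "\n")
        rows.append(
            {
                "trajectory_id": profile.trajectory_id,
                "copy_id": profile.copy_id,
                "condition": profile.condition,
                "provenance": profile.provenance,
                "p3_identity": profile.identities.get(ResidueKey("peptide", 3), ""),
                "path": fname,
            }
        )
    pd.DataFrame(rows).to_csv(out / "manifest.tsv", sep="\t", index=False)
    io_formats.write_coordinates_pdb(study.coords, out / "structure.pdb")
    truth = {
        f.name: getattr(spec, f.name)
        for f in dataclasses.fields(spec)
        if f.name not in ("coupled_blocks", "condition_effects")
    }
    truth["coupled_blocks"] = [
        {
            "members": [str(m) for m in b.members],
            "gamma": b.gamma,
            "beta": b.beta,
        }
        for b in spec.coupled_blocks
    ]
    truth["condition_effects"] = {str(k): v for k, v in spec.condition_effects.items()}
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    return out
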