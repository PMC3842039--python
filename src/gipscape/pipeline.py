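"""End-to-end orchestration, file I/O and residue-region bookkeeping.

FASTA in/out (Biopython-backed, duplicate-ID safe, 60-column wrapping),
1-based-inclusive protein region arithmetic (as used for the AtTSA1
C-terminal interaction domains, e.g. D4 = residues 633–755), a JSON pipeline
config validated by a pydantic schema before any stage runs, and a
``run_pipeline`` driver that executes simulate → scan → phylo in dependency
order, logs every seed, and writes a manifest of output files with SHA-256
checksums. Identical config + seed reproduces identical checksums; run-time
variability (timestamps) is confined to the log.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pydantic import BaseModel, Field, field_validator

from . import identity_phylo, signature, synthetic
from .signature import SEQUENCE_ALPHABET

__all__ = [
    "ProteinRegion",
    "region_length",
    "read_fasta",
    "write_fasta",
    "PipelineConfig",
    "SimulateStage",
    "ScanStage",
    "PhyloStage",
    "run_pipeline",
]

logger = logging.getLogger("gipscape")


@dataclass(frozen=True)
class ProteinRegion:
    """A 1-based inclusive residue interval on a protein."""

    protein_id: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 1:
            raise ValueError("start must be >= 1")
        if self.start > self.end:
            raise ValueError("start must not exceed end")


def region_length(region: ProteinRegion) -> int:
    """Residue count of a 1-based inclusive region: end − start + 1."""
    return region.end - region.start + 1


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into an ordered id → sequence mapping.

    Rejects empty files, duplicate record IDs and illegal residue characters,
    naming the offending record.
    """
    path = Path(path)
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        bad = set(seq) - SEQUENCE_ALPHABET
        if bad:
            raise ValueError(
                f"illegal characters {sorted(bad)} in record {rec.id!r} of {path}"
            )
        records[rec.id] = seq
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    """Write sequences as FASTA wrapped at 60 columns (round-trip safe)."""
    records = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


# --------------------------------------------------------------------------
# pipeline configuration (JSON, schema-validated before any stage runs)


class SimulateStage(BaseModel):
    enabled: bool = True
    n_leaves: int = Field(10, ge=2)
    substitution_rate: float = Field(0.1, ge=0.0)
    preserve_signature: bool = True
    flank_lengths: tuple[int, int] = (18, 18)


class ScanStage(BaseModel):
    enabled: bool = True
    fasta: str | None = None  # defaults to the simulate stage output
    pattern_file: str | None = None  # defaults to the packaged GIP signature


class PhyloStage(BaseModel):
    enabled: bool = True
    fasta: str | None = None
    reference: str | None = None


class PipelineConfig(BaseModel):
    seed: int = 0
    output_dir: str
    simulate: SimulateStage = SimulateStage(enabled=False)
    scan: ScanStage = ScanStage(enabled=False)
    phylo: PhyloStage = PhyloStage(enabled=False)

    @field_validator("seed")
    @classmethod
    def _seed_range(cls, v: int) -> int:
        if not 0 <= v < 2**31:
            raise ValueError("seed must be in [0, 2^31)")
        return v


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _preflight(config: PipelineConfig) -> None:
    """Check every referenced input before any stage writes anything."""
    problems = []
    if config.scan.enabled:
        if config.scan.fasta is None and not config.simulate.enabled:
            problems.append("scan stage needs a fasta path or an enabled simulate stage")
        if config.scan.fasta is not None and not Path(config.scan.fasta).exists():
            problems.append(f"scan fasta not found: {config.scan.fasta}")
        if config.scan.pattern_file is not None and not Path(
            config.scan.pattern_file
        ).exists():
            problems.append(f"pattern file not found: {config.scan.pattern_file}")
    if config.phylo.enabled:
        if config.phylo.fasta is None and not config.simulate.enabled:
            problems.append("phylo stage needs a fasta path or an enabled simulate stage")
        if config.phylo.fasta is not None and not Path(config.phylo.fasta).exists():
            problems.append(f"phylo fasta not found: {config.phylo.fasta}")
    if problems:
        raise FileNotFoundError("; ".join(problems))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in dependency order; return the manifest.

    Outputs are written to stage-scoped subdirectories of ``output_dir``; no
    stage mutates another stage's inputs. The manifest lists every output
    with its SHA-256 checksum and is itself written as ``manifest.json``.
    """
    _preflight(config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    manifest: dict = {"seed": config.seed, "outputs": {}}

    def register(path: Path) -> None:
        manifest["outputs"][str(path.relative_to(outdir))] = _sha256(path)

    try:
        logger.info("pipeline start; global seed=%d", config.seed)
        pattern = signature.load_gip_signature()
        simulated_fasta: Path | None = None

        if config.simulate.enabled:
            t0 = time.perf_counter()
            stage_dir = outdir / "simulate"
            stage_dir.mkdir(exist_ok=True)
            sim = config.simulate
            logger.info("simulate: seed=%d n_leaves=%d rate=%g",
                        config.seed, sim.n_leaves, sim.substitution_rate)
            root = synthetic.gen_signature_sequence(
                pattern, flank_lengths=tuple(sim.flank_lengths), seed=config.seed
            )
            spec = synthetic.FamilySpec(
                substitution_rate=sim.substitution_rate,
                n_leaves=sim.n_leaves,
                preserve_signature=sim.preserve_signature,
                pattern=pattern,
                seed=config.seed,
            )
            leaves, tree = synthetic.evolve_family(root, spec)
            simulated_fasta = stage_dir / "family.faa"
            write_fasta(leaves, simulated_fasta)
            (stage_dir / "true_tree.nwk").write_text(
                identity_phylo.write_newick(tree) + "\n"
            )
            register(simulated_fasta)
            register(stage_dir / "true_tree.nwk")
            logger.info("simulate: done in %.2fs", time.perf_counter() - t0)

        if config.scan.enabled:
            t0 = time.perf_counter()
            stage_dir = outdir / "scan"
            stage_dir.mkdir(exist_ok=True)
            scan_pattern = pattern
            if config.scan.pattern_file is not None:
                scan_pattern = signature.parse_pattern(
                    Path(config.scan.pattern_file).read_text().strip()
                )
            fasta = (
                Path(config.scan.fasta)
                if config.scan.fasta is not None
                else simulated_fasta
            )
            seqs = read_fasta(fasta)
            out = stage_dir / "matches.tsv"
            with open(out, "w") as fh:
                fh.write("seq_id\tstart\tend\tmatched_subsequence\tanchor_position\n")
                for sid, seq in seqs.items():
                    for m in signature.scan_sequence(seq, scan_pattern, sid):
                        anchor = signature.locate_anchor(m, scan_pattern)
                        fh.write(
                            f"{sid}\t{m.start}\t{m.end}\t"
                            f"{m.matched_subsequence}\t{anchor}\n"
                        )
            register(out)
            logger.info("scan: %d sequences in %.2fs", len(seqs),
                        time.perf_counter() - t0)

        if config.phylo.enabled:
            t0 = time.perf_counter()
            stage_dir = outdir / "phylo"
            stage_dir.mkdir(exist_ok=True)
            fasta = (
                Path(config.phylo.fasta)
                if config.phylo.fasta is not None
                else simulated_fasta
            )
            seqs = read_fasta(fasta)
            id_df, dm, ref = identity_phylo.identity_matrix(
                seqs, reference=config.phylo.reference
            )
            id_path = stage_dir / "identities.tsv"
            id_df.to_csv(id_path, sep="\t")
            tree = identity_phylo.nj_tree(dm)
            nwk_path = stage_dir / "tree.nwk"
            nwk_path.write_text(identity_phylo.write_newick(tree) + "\n")
            register(id_path)
            register(nwk_path)
            if ref is not None:
                ref_path = stage_dir / "reference_identity.json"
                ref_path.write_text(json.dumps(ref, indent=2))
                register(ref_path)
                logger.info(
                    "phylo: reference %s identity range %.1f-%.1f%%",
                    ref["reference"], ref["min_identity"], ref["max_identity"],
                )
            logger.info("phylo: %d taxa in %.2fs", len(seqs),
                        time.perf_counter() - t0)

        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        logger.info("pipeline done; %d outputs", len(manifest["outputs"]))
    finally:
        logger.removeHandler(handler)
        handler.close()
    return manifest
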