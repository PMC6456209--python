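"""End-to-end orchestration: extract -> fold -> annotate -> align -> CBC ->
delimit -> tree -> diversity, with per-stage plain-text artifacts.

Every stage writes standard formats (FASTA/Vienna/TSV/Newick) plus a JSON
manifest recording input hashes and parameters, so a stage is skipped on
re-run when nothing it depends on changed, and any stage's artifact can be
replaced by an external tool's output (e.g. structures predicted by a
thermodynamic folding server, supplied via ``structures_in``).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd

from . import annotation, cbc as cbc_mod, delimitation, diversity, phylogeny
from .alignment import StructuralAlignment, encode, align_progressive
from .extract import extract_its2, pad_flanks, passthrough, sequence_stats
from .folding import FoldingParams, SecondaryStructure, fold_suboptimal, select_structure, to_rna
from .io_formats import (
    SequenceSet,
    ViennaRecord,
    get_logger,
    read_fasta,
    read_vienna,
    write_fasta,
    write_newick,
    write_tsv,
    write_vienna,
)

log = get_logger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    input_fasta: str
    outdir: str
    seed: int = 0
    extract: bool = True  # False: input is already bare ITS2
    pad: int = 20
    motif_5p: Optional[str] = None
    motif_3p: Optional[str] = None
    max_mismatch: int = 2
    keep_pads: bool = False  # fold padded, trim pads before alignment
    energy_model: str = "stacking"
    subopt_percent: float = 5.0
    max_structures: int = 50
    structures_in: Optional[str] = None  # external Vienna predictions
    replicates: int = 1000
    distance_model: str = "poisson-12"
    genus_map: Optional[str] = None  # TSV: record <tab> genus
    references: Optional[str] = None  # TSV: record <tab> species name
    community: Optional[str] = None  # isolate table TSV
    segments_per_host: int = 300
    stages: tuple[str, ...] = (
        "extract", "fold", "annotate", "align", "cbc", "delimit", "tree", "diversity",
    )

    def validate(self) -> None:
        for path in (self.input_fasta, self.structures_in, self.genus_map,
                     self.references, self.community):
            if path and not Path(path).exists():
                raise FileNotFoundError(path)


def _sha(*parts: str) -> str:
    h = hashlib.sha256()
    for p in parts:
        h.update(p.encode())
        h.update(b"\x00")
    return h.hexdigest()


def _file_sha(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, outdir: Path):
        self.path = outdir / "manifest.json"
        self.data: dict = {}
        if self.path.exists():
            self.data = json.loads(self.path.read_text())

    def fresh(self, stage: str, key: str, artifacts: list[Path]) -> bool:
        entry = self.data.get(stage)
        return (
            entry is not None
            and entry.get("key") == key
            and all(p.exists() for p in artifacts)
        )

    def record(self, stage: str, key: str, artifacts: list[Path]) -> None:
        self.data[stage] = {"key": key, "artifacts": [str(p) for p in artifacts]}
        self.path.write_text(json.dumps(self.data, indent=2))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages; returns the manifest dictionary.

    A stage failure raises, naming the stage and offending record where
    known; artifacts of completed stages remain on disk.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out)
    in_sha = _file_sha(config.input_fasta)

    # ---- extract -----------------------------------------------------------
    its2_fa = out / "its2.fasta"
    padded_fa = out / "padded.fasta"
    stats_tsv = out / "sequence_stats.tsv"
    key = _sha("extract", in_sha, str(config.extract), str(config.pad),
               str(config.motif_5p), str(config.motif_3p), str(config.max_mismatch))
    if "extract" in config.stages and not manifest.fresh("extract", key, [its2_fa, padded_fa, stats_tsv]):
        try:
            seqs = read_fasta(config.input_fasta)
            recs = []
            for rec in seqs:
                if config.extract:
                    kwargs = {}
                    if config.motif_5p:
                        kwargs["motif_5p"] = config.motif_5p
                    if config.motif_3p:
                        kwargs["motif_3p"] = config.motif_3p
                    r = extract_its2(rec, max_mismatch=config.max_mismatch, **kwargs)
                    r = pad_flanks(r, config.pad)
                else:
                    r = passthrough(rec)
                recs.append(r)
            write_fasta(
                SequenceSet([type(seqs.records[0])(r.id, "", r.its2) for r in recs]), its2_fa
            )
            write_fasta(
                SequenceSet([type(seqs.records[0])(r.id, "", r.padded) for r in recs]),
                padded_fa,
            )
            write_tsv(sequence_stats(recs), stats_tsv)
            # remember pad offsets for later trimming
            offsets = {
                r.id: (r.its2_span[0] - r.padded_span[0], r.padded_span[1] - r.its2_span[1])
                for r in recs
            }
            (out / "pad_offsets.json").write_text(json.dumps(offsets))
        except Exception as exc:
            raise RuntimeError(f"stage 'extract' failed: {exc}") from exc
        manifest.record("extract", key, [its2_fa, padded_fa, stats_tsv])
        log.info("stage extract: %d records", len(recs))
    elif "extract" in config.stages:
        log.info("stage extract: up to date, skipped")

    # ---- fold --------------------------------------------------------------
    vienna_out = out / "structures.vienna"
    if "fold" in config.stages and not manifest.fresh(
        "fold",
        fold_key := _sha("fold", _file_sha(padded_fa), config.energy_model,
                         str(config.subopt_percent), str(config.max_structures),
                         str(config.keep_pads),
                         _file_sha(config.structures_in) if config.structures_in else ""),
        [vienna_out],
    ):
        try:
            offsets = json.loads((out / "pad_offsets.json").read_text())
            structures: list[ViennaRecord] = []
            if config.structures_in:
                structures = read_vienna(config.structures_in)
            else:
                params = FoldingParams(
                    subopt_percent=config.subopt_percent,
                    max_structures=config.max_structures,
                    energy_model=config.energy_model,
                )
                for rec in read_fasta(padded_fa):
                    cands = fold_suboptimal(rec.sequence, params, record_id=rec.id)
                    chosen = select_structure(cands)
                    if not config.keep_pads:
                        chosen = _trim_pads(chosen, offsets.get(rec.id, (0, 0)))
                    structures.append(
                        ViennaRecord(rec.id, _rna_of(rec.sequence, offsets.get(rec.id, (0, 0)), config.keep_pads),
                                     chosen.dotbracket, chosen.energy)
                    )
            write_vienna(structures, vienna_out)
        except Exception as exc:
            raise RuntimeError(f"stage 'fold' failed: {exc}") from exc
        manifest.record("fold", fold_key, [vienna_out])
        log.info("stage fold: %d structures", len(structures))
    elif "fold" in config.stages:
        log.info("stage fold: up to date, skipped")

    # ---- annotate ----------------------------------------------------------
    annot_tsv = out / "annotation.tsv"
    if "annotate" in config.stages and not manifest.fresh(
        "annotate", key := _sha("annotate", _file_sha(vienna_out)), [annot_tsv]
    ):
        try:
            rows = []
            for vr in read_vienna(vienna_out):
                s = SecondaryStructure.from_dotbracket(vr.id, vr.dotbracket, vr.energy or 0.0)
                tree = annotation.build_helix_tree(s)
                topo = annotation.classify_topology(tree)
                motif, variant = annotation.detect_basal_motif(tree, vr.sequence)
                rows.append(
                    {
                        "id": vr.id,
                        "type": topo.type_code,
                        "n_helices": len(tree.principal_helices),
                        "subdomain": tree.subdomain_present,
                        "IIa": tree.iia_present,
                        "helix_lengths": ",".join(
                            str(h.stem_pairs) for h in tree.principal_helices
                        ),
                        "basal_motif": variant,
                        "energy": vr.energy,
                    }
                )
            write_tsv(pd.DataFrame(rows), annot_tsv)
        except Exception as exc:
            raise RuntimeError(f"stage 'annotate' failed: {exc}") from exc
        manifest.record("annotate", key, [annot_tsv])
        log.info("stage annotate: %d records", len(rows))

    # ---- align -------------------------------------------------------------
    aln_fa = out / "alignment.fasta"
    cons_vienna = out / "consensus.vienna"
    cons_tsv = out / "conservation.tsv"
    if "align" in config.stages and not manifest.fresh(
        "align", key := _sha("align", _file_sha(vienna_out)), [aln_fa]
    ):
        try:
            encs = [
                encode(vr.sequence, vr.dotbracket, vr.id) for vr in read_vienna(vienna_out)
            ]
            aln = align_progressive(encs)
            aln.write_fasta(aln_fa)
            if len(encs) >= 2:
                cons = annotation.build_consensus(aln)
                write_vienna(
                    [ViennaRecord("consensus", cons.residues.replace("-", "N"), cons.dotbracket)],
                    cons_vienna,
                )
                write_tsv(
                    pd.DataFrame(
                        {
                            "column": range(1, len(cons.residues) + 1),
                            "residue": list(cons.residues),
                            "conservation": [round(c, 3) for c in cons.conservation],
                            "conserved": cons.conserved,
                        }
                    ),
                    cons_tsv,
                )
        except Exception as exc:
            raise RuntimeError(f"stage 'align' failed: {exc}") from exc
        manifest.record("align", key, [aln_fa])
        log.info("stage align: %d columns", aln.n_columns)

    # ---- cbc ---------------------------------------------------------------
    cbc_tsv = out / "cbc.tsv"
    hemi_tsv = out / "hemicbc.tsv"
    var_tsv = out / "variation.tsv"
    if "cbc" in config.stages and not manifest.fresh(
        "cbc", key := _sha("cbc", _file_sha(aln_fa)), [cbc_tsv, hemi_tsv, var_tsv]
    ):
        try:
            aln = StructuralAlignment.read_fasta(aln_fa)
            mat = cbc_mod.cbc_matrix(aln)
            mat.to_frame("cbc").to_csv(cbc_tsv, sep="\t")
            mat.to_frame("hemi").to_csv(hemi_tsv, sep="\t")
            rows = []
            for a in range(len(aln.ids)):
                for b in range(a + 1, len(aln.ids)):
                    v = cbc_mod.count_variation(aln, aln.ids[a], aln.ids[b])
                    rows.append(
                        {
                            "x": aln.ids[a], "y": aln.ids[b],
                            "transitions": v.transitions,
                            "transversions": v.transversions,
                            "indel_events": v.indel_events,
                            "indel_columns": v.indel_columns,
                        }
                    )
            write_tsv(pd.DataFrame(rows), var_tsv)
        except Exception as exc:
            raise RuntimeError(f"stage 'cbc' failed: {exc}") from exc
        manifest.record("cbc", key, [cbc_tsv, hemi_tsv, var_tsv])
        log.info("stage cbc: done")

    # ---- delimit -----------------------------------------------------------
    part_tsv = out / "partition.tsv"
    if "delimit" in config.stages and not manifest.fresh(
        "delimit",
        key := _sha("delimit", _file_sha(cbc_tsv),
                    _file_sha(config.genus_map) if config.genus_map else "",
                    _file_sha(config.references) if config.references else ""),
        [part_tsv],
    ):
        try:
            cbc_df = pd.read_csv(cbc_tsv, sep="\t", index_col=0)
            hemi_df = pd.read_csv(hemi_tsv, sep="\t", index_col=0)
            mat = cbc_mod.CBCMatrix.from_frame(cbc_df, hemi_df)
            count, part = delimitation.minimal_species_count(mat)
            rows = []
            if config.genus_map:
                genus = dict(
                    pd.read_csv(config.genus_map, sep="\t", header=None).values
                )
                refs = []
                if config.references:
                    refs = [
                        tuple(r)
                        for r in pd.read_csv(config.references, sep="\t", header=None).values
                    ]
                ref_ids = {r for r, _ in refs}
                queries = [rid for rid in mat.ids if rid not in ref_ids]
                aln = StructuralAlignment.read_fasta(aln_fa)

                def ident(q, r):
                    return aln.ungapped(q).letters == aln.ungapped(r).letters

                part = delimitation.assign_species(queries, refs, mat, ident, genus)
                for q in queries:
                    rows.append(
                        {
                            "record": q,
                            "block": part.block_of(q) + 1,
                            "label": part.labels.get(q, ""),
                            "flags": ";".join(part.flags.get(q, [])),
                        }
                    )
            else:
                for rid in mat.ids:
                    rows.append(
                        {
                            "record": rid,
                            "block": part.block_of(rid) + 1,
                            "label": part.labels.get(rid, ""),
                            "flags": "" if part.exact else "greedy",
                        }
                    )
            write_tsv(pd.DataFrame(rows), part_tsv)
            (out / "species_count.json").write_text(
                json.dumps({"minimal_species": part.n_species, "exact": part.exact})
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'delimit' failed: {exc}") from exc
        manifest.record("delimit", key, [part_tsv])
        log.info("stage delimit: %d blocks", part.n_species)

    # ---- tree --------------------------------------------------------------
    tree_nwk = out / "tree.nwk"
    if "tree" in config.stages and not manifest.fresh(
        "tree",
        key := _sha("tree", _file_sha(aln_fa), str(config.replicates), str(config.seed),
                    config.distance_model),
        [tree_nwk],
    ):
        try:
            aln = StructuralAlignment.read_fasta(aln_fa)
            if len(aln.ids) >= 4:
                tree = phylogeny.bootstrap_consensus(
                    aln, replicates=config.replicates, seed=config.seed,
                    model=config.distance_model,
                )
            else:
                tree = phylogeny.neighbor_joining(
                    phylogeny.distance_matrix(aln, model=config.distance_model)
                )
            write_newick(tree, tree_nwk)
        except Exception as exc:
            raise RuntimeError(f"stage 'tree' failed: {exc}") from exc
        manifest.record("tree", key, [tree_nwk])
        log.info("stage tree: written")

    # ---- diversity ---------------------------------------------------------
    if "diversity" in config.stages and config.community:
        div_tsv = out / "diversity.tsv"
        pair_tsv = out / "shared_indices.tsv"
        acc_tsv = out / "accumulation.tsv"
        key = _sha("diversity", _file_sha(config.community), str(config.segments_per_host),
                   str(config.seed))
        if not manifest.fresh("diversity", key, [div_tsv, pair_tsv]):
            try:
                df = pd.read_csv(config.community, sep="\t")
                table = diversity.CommunityTable(
                    df, {h: config.segments_per_host for h in df["host"].unique()}
                )
                write_tsv(diversity.host_report(table), div_tsv)
                write_tsv(diversity.pairwise_report(table), pair_tsv)
                curves = []
                for host in table.hosts:
                    inc = table.incidence(host)
                    if len(inc) >= 1:
                        c = diversity.accumulation_curve(inc, seed=config.seed)
                        frame = c.to_frame()
                        frame.insert(0, "host", host)
                        curves.append(frame)
                if curves:
                    write_tsv(pd.concat(curves, ignore_index=True), acc_tsv)
            except Exception as exc:
                raise RuntimeError(f"stage 'diversity' failed: {exc}") from exc
            manifest.record("diversity", key, [div_tsv, pair_tsv])
            log.info("stage diversity: done")

    return manifest.data


def _rna_of(padded_seq: str, offsets: tuple[int, int], keep_pads: bool) -> str:
    seq = to_rna(padded_seq)
    if keep_pads:
        return seq
    lo, hi = offsets
    return seq[lo : len(seq) - hi if hi else len(seq)]


def _trim_pads(structure: SecondaryStructure, offsets) -> SecondaryStructure:
    """Remove pad columns from a folded structure; pairs that cross into the
    pads are dropped (they are 5.8S/28S proximal stem artifacts)."""
    lo, hi = offsets
    n = len(structure.dotbracket)
    end = n - hi
    pairs = tuple(
        (i - lo, j - lo) for i, j in structure.pairs if lo <= i and j < end
    )
    from .io_formats import pairs_to_dotbracket

    return SecondaryStructure(
        structure.record_id,
        pairs_to_dotbracket(pairs, end - lo),
        pairs,
        structure.energy,
        structure.rank,
        structure.flags,
    )
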