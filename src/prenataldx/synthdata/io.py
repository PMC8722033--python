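"""Serialize a simulated cohort to standard on-disk formats and back.

Writes a VCF 4.2 (GT/GQ/DP plus a per-sample ``LQF`` FORMAT field carrying
the fraction of low-quality bases at the site), BED for truth CNVs (0-based
half-open, matching internal coordinates), TSVs for the bin-count and
exon-depth matrices, a 6-column PED for the trios, and JSON for the genome
model, ontology, phenotypes and full truth set. Reading the files back
reproduces the in-memory objects exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import pysam

from ..trio import Trio
from ..wes_filter import MemberCall, VariantRecord
from .genome import GenomeModel, TruthSet
from .simulate import TrioCohort

__all__ = ["write_fixtures", "read_fixtures", "write_vcf", "read_vcf"]

_INFO_CSQ = {c: c for c in ("missense", "truncating", "splice_region", "synonymous", "intronic", "other")}


def _vcf_header(model: GenomeModel, sample_ids: Sequence[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom, length in model.chromosomes:
        header.contigs.add(chrom, length=length)
    header.add_meta(
        "FORMAT", items=[("ID", "GT"), ("Number", 1), ("Type", "String"), ("Description", "Genotype")]
    )
    header.add_meta(
        "FORMAT", items=[("ID", "GQ"), ("Number", 1), ("Type", "Integer"), ("Description", "Genotype quality")]
    )
    header.add_meta(
        "FORMAT", items=[("ID", "DP"), ("Number", 1), ("Type", "Integer"), ("Description", "Read depth")]
    )
    header.add_meta(
        "FORMAT",
        items=[
            ("ID", "LQF"),
            ("Number", 1),
            ("Type", "Float"),
            ("Description", "Fraction of low-quality bases at the site"),
        ],
    )
    header.add_meta(
        "INFO", items=[("ID", "GENE"), ("Number", 1), ("Type", "String"), ("Description", "Gene id")]
    )
    header.add_meta(
        "INFO", items=[("ID", "CSQ"), ("Number", 1), ("Type", "String"), ("Description", "Consequence")]
    )
    header.add_meta(
        "INFO",
        items=[("ID", "PAF"), ("Number", 1), ("Type", "Float"), ("Description", "Population allele frequency")],
    )
    for s in sample_ids:
        header.add_sample(s)
    return header


def _gt_tuple(genotype: str) -> tuple:
    if genotype in (".", "./."):
        return (None, None)
    if "/" not in genotype:  # hemizygous
        return (int(genotype),)
    a, b = genotype.split("/")
    return (int(a), int(b))


def _gt_string(alleles: tuple) -> str:
    if alleles is None or all(a is None for a in alleles):
        return "./."
    if len(alleles) == 1:
        return str(alleles[0])
    return "/".join(str(a) for a in alleles)


def write_vcf(path: Path, model: GenomeModel, cohort: TrioCohort) -> None:
    """One uncompressed VCF covering all trios (3 sample columns per trio)."""
    sample_ids: list[str] = []
    for trio in cohort.trios:
        sample_ids.extend(trio.member_ids)
    header = _vcf_header(model, sample_ids)
    # collate per-site rows across trios: same site may recur in many trios
    rows: dict[tuple[str, int, str, str], dict] = {}
    for trio in cohort.trios:
        for rec in cohort.records[trio.trio_id]:
            row = rows.setdefault(
                rec.key,
                {"meta": rec, "calls": {}},
            )
            row["calls"][trio.father_id] = rec.father
            row["calls"][trio.mother_id] = rec.mother
            row["calls"][trio.fetus_id] = rec.fetus
    order = {c: i for i, (c, _) in enumerate(model.chromosomes)}
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for key in sorted(rows, key=lambda k: (order.get(k[0], 99), k[1], k[2], k[3])):
            meta: VariantRecord = rows[key]["meta"]
            calls: dict[str, MemberCall] = rows[key]["calls"]
            out = vcf.new_record(
                contig=meta.chrom,
                start=meta.pos - 1,
                alleles=(meta.ref, meta.alt),
            )
            if meta.gene_id:
                out.info["GENE"] = meta.gene_id
            out.info["CSQ"] = meta.consequence
            if meta.population_af is not None:
                out.info["PAF"] = float(meta.population_af)
            for sample in sample_ids:
                call = calls.get(sample)
                if call is None:
                    out.samples[sample]["GT"] = (None, None)
                    continue
                out.samples[sample]["GT"] = _gt_tuple(call.genotype)
                if call.gq is not None:
                    out.samples[sample]["GQ"] = call.gq
                if call.dp is not None:
                    out.samples[sample]["DP"] = call.dp
                if call.lowq_frac is not None:
                    out.samples[sample]["LQF"] = float(call.lowq_frac)
            vcf.write(out)


def read_vcf(path: Path, trios: Sequence[Trio]) -> dict[str, list[VariantRecord]]:
    """Rebuild per-trio variant records from a cohort VCF."""
    out: dict[str, list[VariantRecord]] = {t.trio_id: [] for t in trios}
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            paf = rec.info.get("PAF")
            for trio in trios:
                calls = {}
                for member, sample in zip(
                    ("father", "mother", "fetus"), trio.member_ids
                ):
                    fmt = rec.samples[sample]
                    gt = _gt_string(fmt.get("GT"))
                    if gt == "./.":
                        calls[member] = MemberCall()
                        continue
                    lqf = fmt.get("LQF")
                    calls[member] = MemberCall(
                        genotype=gt,
                        gq=fmt.get("GQ"),
                        dp=fmt.get("DP"),
                        lowq_frac=round(float(lqf), 6) if lqf is not None else None,
                    )
                if all(c.is_missing for c in calls.values()):
                    continue
                out[trio.trio_id].append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=rec.alts[0],
                        gene_id=rec.info.get("GENE"),
                        consequence=rec.info.get("CSQ", "other"),
                        population_af=round(float(paf), 6) if paf is not None else None,
                        **calls,
                    )
                )
    for records in out.values():
        records.sort(key=lambda r: (r.chrom, r.pos))
    return out


def write_fixtures(
    out_dir: Path,
    model: GenomeModel,
    cohort: TrioCohort,
    bincounts: pd.DataFrame | None = None,
    exondepth: pd.DataFrame | None = None,
    exons: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write the cohort artifact set; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["model"] = out_dir / "model.json"
    paths["model"].write_text(model.to_json())

    paths["ontology"] = out_dir / "ontology.json"
    paths["ontology"].write_text(json.dumps(model.ontology.to_dict(), indent=1))

    paths["truth"] = out_dir / "truth.json"
    paths["truth"].write_text(json.dumps(cohort.truth.to_dict(), indent=1))

    paths["phenotypes"] = out_dir / "phenotypes.json"
    paths["phenotypes"].write_text(
        json.dumps({t: sorted(terms) for t, terms in cohort.phenotypes.items()}, indent=1)
    )

    paths["pedigree"] = out_dir / "trios.ped"
    with open(paths["pedigree"], "w") as fh:
        for trio in cohort.trios:
            sex = 1 if trio.fetal_sex == "male" else 2
            fh.write(
                f"{trio.trio_id}\t{trio.fetus_id}\t{trio.father_id}\t{trio.mother_id}\t{sex}\t2\n"
            )
            fh.write(f"{trio.trio_id}\t{trio.father_id}\t0\t0\t1\t1\n")
            fh.write(f"{trio.trio_id}\t{trio.mother_id}\t0\t0\t2\t1\n")

    paths["vcf"] = out_dir / "trios.vcf"
    write_vcf(paths["vcf"], model, cohort)

    paths["truth_cnv"] = out_dir / "truth_cnv.bed"
    with open(paths["truth_cnv"], "w") as fh:
        for cnv in cohort.truth.planted_cnvs:
            name = f"{cnv.sample_id}|copies={cnv.copies}|origin={cnv.parental_origin}|channel={cnv.channel}"
            fh.write(f"{cnv.chrom}\t{cnv.start}\t{cnv.end}\t{name}\n")

    if bincounts is not None:
        paths["bincounts"] = out_dir / "bincounts.tsv"
        bincounts.to_csv(paths["bincounts"], sep="\t", index=False)
    if exondepth is not None:
        paths["exondepth"] = out_dir / "exondepth.tsv"
        tidy = exondepth.copy()
        tidy.insert(0, "sample_id", tidy.index)
        tidy.to_csv(paths["exondepth"], sep="\t", index=False)
        if exons is not None:
            paths["exons"] = out_dir / "exons.tsv"
            exons.to_csv(paths["exons"], sep="\t", index=False)
    return paths


def read_fixtures(out_dir: Path) -> tuple[GenomeModel, TrioCohort]:
    """Inverse of :func:`write_fixtures` for the cohort objects."""
    out_dir = Path(out_dir)
    model = GenomeModel.from_dict(json.loads((out_dir / "model.json").read_text()))
    truth = TruthSet.from_dict(json.loads((out_dir / "truth.json").read_text()))
    phenotypes = {
        t: frozenset(terms)
        for t, terms in json.loads((out_dir / "phenotypes.json").read_text()).items()
    }
    trios: dict[str, dict] = {}
    with open(out_dir / "trios.ped") as fh:
        for line in fh:
            fam, iid, father, mother, sex, phe = line.split()
            entry = trios.setdefault(fam, {})
            if father != "0":
                entry["fetus_id"] = iid
                entry["father_id"] = father
                entry["mother_id"] = mother
                entry["fetal_sex"] = "male" if sex == "1" else "female"
    trio_objs = [
        Trio(trio_id=fam, **fields) for fam, fields in sorted(trios.items())
    ]
    records = read_vcf(out_dir / "trios.vcf", trio_objs)
    cohort = TrioCohort(
        trios=trio_objs, records=records, phenotypes=phenotypes, truth=truth
    )
    return model, cohort
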