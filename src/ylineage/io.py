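"""Readers and writers for the formats the pipeline touches.

Haplotype matrices travel as TSV (sample, population, then one column per
locus; derived calls as the derived base, ``-`` for the ancestral state,
``X`` for missing), per-site call tables as VCF 4.x or a long-format TSV,
and networks as GraphML or DOT.  VCF positions are 1-based; internal site
indices are 0-based; conversion happens only here.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .depth import DepthProfile
from .matrix import Call, HaplotypeMatrix, SampleDef, SiteDef

_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}

#: Names under which the female-amplifying locus dropped from the validated
#: panel appears in different parts of the source study; the discrepancy is
#: preserved rather than resolved.
EXCLUDED_LOCUS_ALIASES = ("20_357AT", "20_349AT")


# ---------------------------------------------------------------------------
# haplotype matrix TSV
# ---------------------------------------------------------------------------

def read_haplotype_matrix(
    path: str | Path,
    sites_path: str | Path | None = None,
    samples_path: str | Path | None = None,
    ancestral_id: str = "Ancestral",
) -> HaplotypeMatrix:
    """Read a samples x sites haplotype TSV.

    The first column is the sample identifier, the second the population
    label, and each further column one locus.  A row whose identifier equals
    ``ancestral_id`` supplies the ancestral alleles and is not kept as a
    sample.  Optional sidecar TSVs supply site definitions (alleles, assayed
    flags) and sample provenance (sequenced/genotyped); without them the
    alleles are inferred from the matrix itself.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3:
            raise ValueError(f"{path}: header must name at least one locus")
        locus_ids = header[2:]
        rows: list[tuple[str, str, list[str]]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}: row {lineno} ({fields[0]!r}) has {len(fields)} "
                    f"fields, expected {len(header)}"
                )
            rows.append((fields[0], fields[1], fields[2:]))

    site_meta = _read_site_meta(sites_path) if sites_path else {}
    sample_meta = _read_sample_meta(samples_path) if samples_path else {}

    ancestral = None
    for sid, _pop, chars in rows:
        if sid == ancestral_id:
            ancestral = chars
            break
    if ancestral is None and not site_meta:
        raise ValueError(
            f"{path}: no ancestral row {ancestral_id!r} and no site metadata; "
            "the ancestral state cannot be determined"
        )

    sites: list[SiteDef] = []
    for j, locus in enumerate(locus_ids):
        if locus in site_meta:
            sites.append(site_meta[locus])
            continue
        anc = ancestral[j]
        observed = {
            c for sid, _pop, chars in rows
            if sid != ancestral_id and (c := chars[j]) not in ("-", "X")
        } - {anc}
        if len(observed) > 1:
            raise ValueError(
                f"{path}: locus {locus} shows more than one derived allele "
                f"({sorted(observed)}); only bi-allelic sites are supported"
            )
        derived = observed.pop() if observed else _TRANSITION_PARTNER.get(anc)
        sites.append(SiteDef(locus_id=locus, ancestral_allele=anc,
                             derived_allele=derived))
    if ancestral is not None:
        for j, site in enumerate(sites):
            if site.ancestral_allele != ancestral[j]:
                raise ValueError(
                    f"{path}: ancestral row has {ancestral[j]!r} at "
                    f"{site.locus_id} but site metadata says "
                    f"{site.ancestral_allele!r}"
                )

    samples: list[SampleDef] = []
    call_rows: list[list[int]] = []
    for sid, pop, chars in rows:
        if sid == ancestral_id:
            continue
        meta = sample_meta.get(sid)
        samples.append(
            meta if meta is not None
            else SampleDef(identifier=sid, population=pop)
        )
        row = []
        for j, c in enumerate(chars):
            site = sites[j]
            if c == "-" or c == site.ancestral_allele:
                row.append(Call.ANCESTRAL)
            elif c == "X":
                row.append(Call.MISSING)
            elif c == site.derived_allele:
                row.append(Call.DERIVED)
            else:
                raise ValueError(
                    f"{path}: sample {sid} carries {c!r} at {site.locus_id}, "
                    f"which matches neither allele "
                    f"({site.ancestral_allele}/{site.derived_allele})"
                )
        call_rows.append(row)

    return HaplotypeMatrix(sites, samples, np.array(call_rows, dtype=np.int8))


def _read_site_meta(path: str | Path) -> dict[str, SiteDef]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = {}
    for _, r in df.iterrows():
        pos = r.get("position_on_reference", "")
        out[r["locus_id"]] = SiteDef(
            locus_id=r["locus_id"],
            ancestral_allele=r["ancestral_allele"],
            derived_allele=r["derived_allele"],
            assayed=r.get("assayed", "0") == "1",
            source_fragment=r.get("source_fragment", ""),
            position_on_reference=int(pos) if pos else None,
        )
    return out


def _read_sample_meta(path: str | Path) -> dict[str, SampleDef]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return {
        r["sample"]: SampleDef(
            identifier=r["sample"],
            population=r.get("population", ""),
            sequenced=r.get("sequenced", "1") == "1",
            genotyped=r.get("genotyped", "0") == "1",
        )
        for _, r in df.iterrows()
    }


def write_haplotype_matrix(
    m: HaplotypeMatrix,
    path: str | Path,
    sites_path: str | Path | None = None,
    samples_path: str | Path | None = None,
    ancestral_id: str = "Ancestral",
) -> None:
    """Write a matrix in the TSV dialect read by :func:`read_haplotype_matrix`."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("sample\tpopulation\t" + "\t".join(m.locus_ids) + "\n")
        fh.write(
            f"{ancestral_id}\t\t"
            + "\t".join(s.ancestral_allele for s in m.sites)
            + "\n"
        )
        for i, s in enumerate(m.samples):
            chars = []
            for j, site in enumerate(m.sites):
                code = m.calls[i, j]
                chars.append(
                    "-" if code == Call.ANCESTRAL
                    else "X" if code == Call.MISSING
                    else site.derived_allele
                )
            fh.write(f"{s.identifier}\t{s.population}\t" + "\t".join(chars) + "\n")
    if sites_path:
        with open(sites_path, "w") as fh:
            fh.write("locus_id\tancestral_allele\tderived_allele\tassayed\t"
                     "source_fragment\tposition_on_reference\n")
            for s in m.sites:
                pos = "" if s.position_on_reference is None else str(s.position_on_reference)
                fh.write(f"{s.locus_id}\t{s.ancestral_allele}\t{s.derived_allele}\t"
                         f"{int(s.assayed)}\t{s.source_fragment}\t{pos}\n")
    if samples_path:
        with open(samples_path, "w") as fh:
            fh.write("sample\tpopulation\tsequenced\tgenotyped\n")
            for s in m.samples:
                fh.write(f"{s.identifier}\t{s.population}\t"
                         f"{int(s.sequenced)}\t{int(s.genotyped)}\n")


def load_table1() -> HaplotypeMatrix:
    """The packaged 19-fox x 31-site haplotype panel with its ancestral row.

    Thirteen loci carry a validated male-specific assay; two samples were
    genotyped at those loci but not (successfully) sequenced, so they are
    missing at the 18 unassayed sites.  The female-amplifying locus excluded
    from the panel is recorded in ``metadata['excluded_locus_aliases']``.
    """
    data = importlib.resources.files("ylineage") / "data"
    m = read_haplotype_matrix(
        data / "table1_calls.tsv",
        sites_path=data / "table1_sites.tsv",
        samples_path=data / "table1_samples.tsv",
    )
    m.metadata["excluded_locus_aliases"] = EXCLUDED_LOCUS_ALIASES
    m.metadata["source"] = "table1"
    return m


# ---------------------------------------------------------------------------
# per-site call tables (VCF / TSV)
# ---------------------------------------------------------------------------

@dataclass
class CallTable:
    """Per-site per-sample calls and depths extracted from a variant file.

    ``calls`` is a long-format frame (site_index, chrom, pos, sample, call)
    where heterozygous genotypes appear as MISSING with the site's het flag
    set — on a haploid Y a het call marks paralogy, never an allele.
    Multi-allelic sites are listed for downstream filtering, never silently
    kept.
    """

    profiles: list[DepthProfile]
    calls: pd.DataFrame
    samples: list[str]
    multiallelic_sites: list[int] = field(default_factory=list)


def read_call_table(path: str | Path, format: str = "vcf") -> CallTable:
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_call_tsv(path)
    raise ValueError(f"unknown call-table format {format!r}")


def _read_vcf(path: str | Path) -> CallTable:
    import pysam

    vf = pysam.VariantFile(str(path))
    if "DP" not in vf.header.formats:
        raise ValueError(f"{path}: VCF FORMAT lacks the DP (depth) field")
    samples = list(vf.header.samples)
    profiles: list[DepthProfile] = []
    records = []
    multiallelic = []
    for idx, rec in enumerate(vf):
        alts = rec.alts or ()
        if len(alts) > 1:
            multiallelic.append(idx)
        depths = []
        het = False
        for s in samples:
            sm = rec.samples[s]
            dp = sm.get("DP")
            if dp is None:
                raise ValueError(
                    f"{path}: sample {s} at {rec.chrom}:{rec.pos} lacks DP"
                )
            depths.append(int(dp))
            gt = sm.get("GT")
            alleles = [a for a in (gt or ()) if a is not None]
            if len(set(alleles)) > 1:
                het = True
                call = Call.MISSING  # paralogy flag, not an allele
            elif not alleles:
                call = Call.MISSING
            else:
                call = Call.DERIVED if alleles[0] > 0 else Call.ANCESTRAL
            records.append(
                {"site_index": idx, "chrom": rec.chrom, "pos": rec.pos,
                 "sample": s, "call": call.name}
            )
        profiles.append(
            DepthProfile(site_index=idx, pooled_depth=sum(depths),
                         per_sample_depth=tuple(depths), het_flag=het)
        )
    return CallTable(profiles=profiles, calls=pd.DataFrame(records),
                     samples=samples, multiallelic_sites=multiallelic)


def _read_call_tsv(path: str | Path) -> CallTable:
    df = pd.read_csv(path, sep="\t", dtype={"gt": str})
    required = {"chrom", "pos", "sample", "gt", "dp"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: call TSV lacks columns {sorted(missing)}")
    samples = sorted(df["sample"].unique())
    profiles = []
    records = []
    multiallelic: list[int] = []
    for idx, ((chrom, pos), grp) in enumerate(
        df.groupby(["chrom", "pos"], sort=True)
    ):
        depths = {}
        het = False
        for _, r in grp.iterrows():
            depths[r["sample"]] = int(r["dp"])
            gt = str(r["gt"])
            alleles = [a for a in gt.replace("|", "/").split("/") if a != "."]
            if len(set(alleles)) > 1:
                het = True
                call = Call.MISSING
            elif not alleles:
                call = Call.MISSING
            else:
                call = Call.DERIVED if int(alleles[0]) > 0 else Call.ANCESTRAL
            records.append({"site_index": idx, "chrom": chrom, "pos": int(pos),
                            "sample": r["sample"], "call": call.name})
        per = tuple(depths.get(s, 0) for s in samples)
        profiles.append(DepthProfile(site_index=idx, pooled_depth=sum(per),
                                     per_sample_depth=per, het_flag=het))
    return CallTable(profiles=profiles, calls=pd.DataFrame(records),
                     samples=samples, multiallelic_sites=multiallelic)


# ---------------------------------------------------------------------------
# networks (GraphML / DOT)
# ---------------------------------------------------------------------------

def write_network(net, path: str | Path, format: str = "graphml") -> None:
    """Externalize a haplotype network with all node/edge annotations."""
    import networkx as nx

    path = Path(path)
    g = nx.Graph()
    g.graph["epsilon"] = int(net.epsilon)
    g.graph["site_ids"] = ",".join(net.site_ids)
    for node, attrs in net.graph.nodes(data=True):
        g.add_node(
            node,
            state="".join(str(int(x)) for x in attrs["state"]),
            multiplicity=int(attrs["multiplicity"]),
            labels=",".join(attrs["labels"]),
            populations=",".join(attrs["populations"]),
            is_median=bool(attrs["is_median"]),
            is_root=bool(attrs["is_root"]),
        )
    for a, b, attrs in net.graph.edges(data=True):
        g.add_edge(a, b, weight=int(attrs["weight"]),
                   loci=",".join(attrs["loci"]))
    if format == "graphml":
        nx.write_graphml(g, str(path))
    elif format == "dot":
        _write_dot(g, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def _write_dot(g, path: Path) -> None:
    def q(v):
        return '"' + str(v).replace('"', r"\"") + '"'

    with open(path, "w") as fh:
        fh.write("graph haplotype_network {\n")
        fh.write(f"  graph [epsilon={q(g.graph['epsilon'])}, "
                 f"site_ids={q(g.graph['site_ids'])}];\n")
        for node, a in sorted(g.nodes(data=True)):
            fh.write(
                f"  {q(node)} [state={q(a['state'])}, "
                f"multiplicity={q(a['multiplicity'])}, labels={q(a['labels'])}, "
                f"populations={q(a['populations'])}, "
                f"is_median={q(int(a['is_median']))}, "
                f"is_root={q(int(a['is_root']))}];\n"
            )
        for a, b, attrs in sorted(g.edges(data=True)):
            fh.write(f"  {q(a)} -- {q(b)} [weight={q(attrs['weight'])}, "
                     f"loci={q(attrs['loci'])}];\n")
        fh.write("}\n")


def read_network(path: str | Path, format: str = "graphml"):
    import networkx as nx

    from .network import NetworkGraph

    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(str(path))
    elif format == "dot":
        g = _read_dot(path)
    else:
        raise ValueError(f"unknown network format {format!r}")

    site_ids = [s for s in str(g.graph.get("site_ids", "")).split(",") if s]
    epsilon = int(g.graph.get("epsilon", 0))
    out = nx.Graph()
    root = None
    for node, a in g.nodes(data=True):
        state = np.array([int(c) for c in str(a["state"])], dtype=np.uint8)
        is_root = a["is_root"] in (True, "True", "true", "1", 1)
        is_median = a["is_median"] in (True, "True", "true", "1", 1)
        labels = tuple(x for x in str(a.get("labels", "")).split(",") if x)
        pops = tuple(x for x in str(a.get("populations", "")).split(",") if x)
        out.add_node(node, state=state, multiplicity=int(a["multiplicity"]),
                     labels=labels, populations=pops,
                     is_median=is_median, is_root=is_root)
        if is_root:
            root = node
    for a, b, attrs in g.edges(data=True):
        loci = tuple(x for x in str(attrs.get("loci", "")).split(",") if x)
        out.add_edge(a, b, weight=int(attrs["weight"]), loci=loci)
    return NetworkGraph(out, site_ids=site_ids, epsilon=epsilon, root=root)


_DOT_NODE = None  # compiled lazily


def _read_dot(path: Path):
    """Minimal parser for the DOT dialect emitted by :func:`_write_dot`."""
    import re

    import networkx as nx

    attr_re = re.compile(r'(\w+)="((?:[^"\\]|\\.)*)"')
    node_re = re.compile(r'^\s*"((?:[^"\\]|\\.)*)"\s*\[(.*)\];\s*$')
    edge_re = re.compile(
        r'^\s*"((?:[^"\\]|\\.)*)"\s*--\s*"((?:[^"\\]|\\.)*)"\s*\[(.*)\];\s*$'
    )
    graph_re = re.compile(r"^\s*graph\s*\[(.*)\];\s*$")

    def unq(s: str) -> str:
        return s.replace(r"\"", '"')

    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            if m := edge_re.match(line):
                attrs = {k: unq(v) for k, v in attr_re.findall(m.group(3))}
                g.add_edge(unq(m.group(1)), unq(m.group(2)), **attrs)
            elif m := node_re.match(line):
                attrs = {k: unq(v) for k, v in attr_re.findall(m.group(2))}
                g.add_node(unq(m.group(1)), **attrs)
            elif m := graph_re.match(line):
                g.graph.update(
                    {k: unq(v) for k, v in attr_re.findall(m.group(1))}
                )
    return g
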