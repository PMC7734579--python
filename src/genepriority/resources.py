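"""Data model and on-disk formats for a prioritization resource bundle.

A bundle is a directory of plain-text files mirroring the public resources
the pipeline draws on: a protein-coding gene universe, the candidate gene
list, a genes x brain-regions TPM matrix, process and phenotype ontologies
(OBO), direct gene->term annotations, cross-species ortholog predictions,
knockout phenotype associations, drug target development levels,
pharmacogenomic variants, a protein-protein interaction edge list, the
clinically actionable gene panel, and pathogenicity labels.

All tables are tab-delimited UTF-8 with '#'-prefixed comment lines ignored
and a header on the first non-comment line.  Gene identity is a single
opaque identifier string used as the join key everywhere; symbols are
display-only.  Unknown gene ids in secondary tables are dropped with a
logged count rather than raised, because real resources cover different
gene universes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import obonet
import pandas as pd

from .ontology import OntologyDAG

logger = logging.getLogger(__name__)

DRUG_LEVELS = ("Tclin", "Tchem", "Tbio", "Tdark")
PATHOGENIC_LABELS = ("pathogenic", "likely_pathogenic", "other")
SEXES = ("female", "male", "both")

#: default file names inside a bundle directory
BUNDLE_FILES = {
    "universe": "universe.tsv",
    "candidates": "candidates.txt",
    "expression": "expression.tsv",
    "ontology_human": "ontology_human.obo",
    "ontology_mouse": "ontology_mouse.obo",
    "ontology_mp": "ontology_mp.obo",
    "annotations_human": "annotations_human.tsv",
    "annotations_mouse": "annotations_mouse.tsv",
    "orthologs": "orthologs.tsv",
    "phenotypes": "phenotypes.tsv",
    "drug_targets": "drug_targets.tsv",
    "pgx": "pgx.tsv",
    "network": "network.tsv",
    "actionable": "actionable.txt",
    "labels": "labels.tsv",
    "xmap": "xmap.tsv",
}


class GeneUniverse:
    """Ordered collection of gene records (id, symbol, protein-coding flag).

    Only protein-coding genes participate in sampling and annotation.
    Order is preserved exactly as loaded; downstream outputs are stable
    under it.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"id", "symbol", "protein_coding"}
        if not required <= set(table.columns):
            raise ValueError(f"universe table needs columns {sorted(required)}")
        if table.empty:
            raise ValueError("gene universe is empty")
        if table["id"].duplicated().any():
            dups = table.loc[table["id"].duplicated(), "id"].head().tolist()
            raise ValueError(f"duplicate gene ids in universe: {dups}")
        t = table.copy().reset_index(drop=True)
        t["protein_coding"] = t["protein_coding"].astype(int).astype(bool)
        self.table = t
        self._ids = t["id"].tolist()
        self._coding = t.loc[t["protein_coding"], "id"].tolist()
        self._id_set = frozenset(self._ids)
        self.symbols = dict(zip(t["id"], t["symbol"]))

    @property
    def ids(self) -> list[str]:
        return list(self._ids)

    @property
    def coding_ids(self) -> list[str]:
        return list(self._coding)

    def __contains__(self, gene: str) -> bool:
        return gene in self._id_set

    def __len__(self) -> int:
        return len(self._ids)

    def equals(self, other: "GeneUniverse") -> bool:
        return self.table.equals(other.table)


@dataclass
class ResourceBundle:
    """Every input table/ontology for one pipeline run, keyed by gene id."""

    universe: GeneUniverse
    candidates: list[str]
    expression: pd.DataFrame            # index: gene id; columns: region names; TPM
    ontology_human: OntologyDAG
    ontology_mouse: OntologyDAG
    ontology_mp: OntologyDAG
    annotations_human: dict[str, frozenset[str]]
    annotations_mouse: dict[str, frozenset[str]]
    orthologs: pd.DataFrame             # source, target, support_count, best_forward, best_reverse
    phenotypes: pd.DataFrame            # gene, mp_term, p_value, sex
    drug_targets: pd.DataFrame          # gene, level
    pgx: pd.DataFrame                   # gene, variant, significant, guideline
    network: pd.DataFrame               # protein_a, protein_b, confidence
    actionable: list[str]
    labels: pd.DataFrame                # gene, label
    xmap: pd.DataFrame                  # source_term, target_term, distance
    truth: pd.DataFrame | None = None   # synthetic-only: planted/realized flags

    @property
    def mouse_genes(self) -> list[str]:
        """Mouse gene universe: every predicted ortholog target."""
        return sorted(set(self.orthologs["target"]) | set(self.annotations_mouse))


# ---------------------------------------------------------------------------
# readers


def _read_tsv(path: Path, required: Iterable[str]) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"missing bundle file: {path}")
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", dtype={"id": str}, float_precision="round_trip"
        )
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise ValueError(f"malformed table {path.name}: {exc}") from exc
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path.name}: missing columns {sorted(missing)}")
    bad = df[list(required)].isna()
    if bad.any().any():
        row = int(bad.any(axis=1).idxmax())
        # +2: header line and 1-based numbering
        raise ValueError(f"{path.name}: malformed line {row + 2}")
    return df


def _read_list(path: Path) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(f"missing bundle file: {path}")
    out = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def read_obo(path: Path) -> OntologyDAG:
    """Load an OBO ontology; only id, name and is_a tags are honored."""
    if not Path(path).exists():
        raise FileNotFoundError(f"missing bundle file: {path}")
    multi = obonet.read_obo(str(path))
    g = nx.DiGraph()
    g.add_nodes_from(multi.nodes)
    names = {}
    for node, data in multi.nodes(data=True):
        if "name" in data:
            names[node] = data["name"]
    for child, parent, key in multi.edges(keys=True):
        if key == "is_a":
            g.add_edge(child, parent)
    return OntologyDAG(g, names)


def read_annotations(path: Path) -> dict[str, frozenset[str]]:
    """Gene -> term map from a two-column TSV (gene, term) or GMT file."""
    path = Path(path)
    if path.suffix == ".gmt":
        if not path.exists():
            raise FileNotFoundError(f"missing bundle file: {path}")
        out: dict[str, set[str]] = {}
        for i, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path.name}: malformed line {i}")
            term = parts[0]
            for gene in parts[2:]:
                if gene:
                    out.setdefault(gene, set()).add(term)
        return {g: frozenset(ts) for g, ts in out.items()}
    df = _read_tsv(path, ["gene", "term"])
    grouped = df.groupby("gene")["term"].apply(frozenset)
    return grouped.to_dict()


def _drop_unknown(df: pd.DataFrame, col: str, known: frozenset[str], what: str) -> pd.DataFrame:
    mask = df[col].isin(known)
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.warning("%s: dropped %d records with unknown gene ids", what, n_dropped)
    return df[mask].reset_index(drop=True)


def load_bundle(directory: Path, files: dict[str, str] | None = None) -> ResourceBundle:
    """Load and validate a resource bundle from a directory of text files.

    Missing files and malformed lines are fatal; candidate genes absent
    from the universe are dropped with a warning; unknown gene ids in
    secondary tables are dropped with a logged count.
    """
    directory = Path(directory)
    f = dict(BUNDLE_FILES)
    if files:
        f.update(files)

    universe = GeneUniverse(_read_tsv(directory / f["universe"], ["id", "symbol", "protein_coding"]))
    known = frozenset(universe.ids)

    candidates = _read_list(directory / f["candidates"])
    kept = [g for g in candidates if g in known]
    if len(kept) < len(candidates):
        logger.warning(
            "candidates: dropped %d genes absent from universe", len(candidates) - len(kept)
        )
    candidates = kept

    expr_raw = _read_tsv(directory / f["expression"], ["id"])
    expr = expr_raw.set_index("id")
    expr.columns.name = None
    if expr.columns.duplicated().any():
        raise ValueError("expression: duplicate region names")
    if expr.shape[1] < 1:
        raise ValueError("expression: needs at least one region column")
    expr = expr.astype(float)
    if (expr < 0).any().any():
        col = expr.columns[(expr < 0).any().values][0]
        row = expr.index[(expr[col] < 0).values][0]
        raise ValueError(f"expression: negative TPM at gene {row!r}, region {col!r}")
    unknown_rows = [g for g in expr.index if g not in known]
    if unknown_rows:
        logger.warning("expression: dropped %d rows with unknown gene ids", len(unknown_rows))
        expr = expr.drop(index=unknown_rows)

    ontology_human = read_obo(directory / f["ontology_human"])
    ontology_mouse = read_obo(directory / f["ontology_mouse"])
    ontology_mp = read_obo(directory / f["ontology_mp"])

    annotations_human = read_annotations(directory / f["annotations_human"])
    annotations_human = {g: t for g, t in annotations_human.items() if g in known}
    annotations_mouse = read_annotations(directory / f["annotations_mouse"])

    orthologs = _read_tsv(
        directory / f["orthologs"],
        ["source", "target", "support_count", "best_forward", "best_reverse"],
    )
    orthologs["support_count"] = orthologs["support_count"].astype(int)
    if (orthologs["support_count"] < 0).any():
        raise ValueError("orthologs: negative support_count")
    for c in ("best_forward", "best_reverse"):
        orthologs[c] = orthologs[c].astype(int).astype(bool)
    orthologs = _drop_unknown(orthologs, "source", known, "orthologs")

    phenotypes = _read_tsv(directory / f["phenotypes"], ["gene", "mp_term", "p_value", "sex"])
    phenotypes["p_value"] = phenotypes["p_value"].astype(float)
    if ((phenotypes["p_value"] < 0) | (phenotypes["p_value"] > 1)).any():
        raise ValueError("phenotypes: p_value outside [0, 1]")
    bad_sex = ~phenotypes["sex"].isin(SEXES)
    if bad_sex.any():
        raise ValueError(f"phenotypes: invalid sex value {phenotypes.loc[bad_sex, 'sex'].iloc[0]!r}")

    drug_targets = _read_tsv(directory / f["drug_targets"], ["gene", "level"])
    bad = ~drug_targets["level"].isin(DRUG_LEVELS)
    if bad.any():
        raise ValueError(f"drug_targets: invalid level {drug_targets.loc[bad, 'level'].iloc[0]!r}")
    if drug_targets["gene"].duplicated().any():
        raise ValueError("drug_targets: more than one level for a gene")
    drug_targets = _drop_unknown(drug_targets, "gene", known, "drug_targets")

    pgx = _read_tsv(directory / f["pgx"], ["gene", "variant", "significant"])
    pgx["significant"] = pgx["significant"].astype(int).astype(bool)
    if "guideline" not in pgx.columns:
        pgx["guideline"] = ""
    pgx["guideline"] = pgx["guideline"].fillna("")
    pgx = _drop_unknown(pgx, "gene", known, "pgx")

    network = _read_tsv(directory / f["network"], ["protein_a", "protein_b", "confidence"])
    network["confidence"] = network["confidence"].astype(float)
    if ((network["confidence"] < 0) | (network["confidence"] > 1)).any():
        raise ValueError("network: confidence outside [0, 1]")
    if (network["protein_a"] == network["protein_b"]).any():
        raise ValueError("network: self-loop edge")

    actionable = _read_list(directory / f["actionable"])

    labels = _read_tsv(directory / f["labels"], ["gene", "label"])
    bad = ~labels["label"].isin(PATHOGENIC_LABELS)
    if bad.any():
        raise ValueError(f"labels: invalid label {labels.loc[bad, 'label'].iloc[0]!r}")
    if labels["gene"].duplicated().any():
        raise ValueError("labels: more than one label for a gene")
    labels = _drop_unknown(labels, "gene", known, "labels")

    xmap = _read_tsv(directory / f["xmap"], ["source_term", "target_term", "distance"])
    xmap["distance"] = xmap["distance"].astype(int)
    if (xmap["distance"] < 1).any():
        raise ValueError("xmap: distance must be a positive integer")

    truth_path = directory / "truth.tsv"
    truth = (
        pd.read_csv(truth_path, sep="\t", comment="#", float_precision="round_trip")
        if truth_path.exists()
        else None
    )

    return ResourceBundle(
        universe=universe,
        candidates=candidates,
        expression=expr,
        ontology_human=ontology_human,
        ontology_mouse=ontology_mouse,
        ontology_mp=ontology_mp,
        annotations_human=annotations_human,
        annotations_mouse=annotations_mouse,
        orthologs=orthologs,
        phenotypes=phenotypes,
        drug_targets=drug_targets,
        pgx=pgx,
        network=network,
        actionable=actionable,
        labels=labels,
        xmap=xmap,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# writers


def write_obo(dag: OntologyDAG, path: Path, ontology_name: str = "synthetic") -> None:
    lines = [f"format-version: 1.2", f"ontology: {ontology_name}", ""]
    for term in sorted(dag.terms):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        name = dag.names.get(term)
        if name:
            lines.append(f"name: {name}")
        for parent in sorted(dag.parents(term)):
            lines.append(f"is_a: {parent}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def _write_annotations(ann: dict[str, frozenset[str]], path: Path) -> None:
    rows = [(g, t) for g in sorted(ann) for t in sorted(ann[g])]
    pd.DataFrame(rows, columns=["gene", "term"]).to_csv(path, sep="\t", index=False)


def save_bundle(bundle: ResourceBundle, directory: Path, files: dict[str, str] | None = None) -> None:
    """Write a bundle to a directory in the formats `load_bundle` reads."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    f = dict(BUNDLE_FILES)
    if files:
        f.update(files)

    uni = bundle.universe.table.copy()
    uni["protein_coding"] = uni["protein_coding"].astype(int)
    uni.to_csv(directory / f["universe"], sep="\t", index=False)

    (directory / f["candidates"]).write_text("\n".join(bundle.candidates) + "\n")
    # %.17g guarantees exact float round trips through the text format
    bundle.expression.rename_axis("id").to_csv(
        directory / f["expression"], sep="\t", float_format="%.17g"
    )

    write_obo(bundle.ontology_human, directory / f["ontology_human"], "process-human")
    write_obo(bundle.ontology_mouse, directory / f["ontology_mouse"], "process-mouse")
    write_obo(bundle.ontology_mp, directory / f["ontology_mp"], "phenotype")

    _write_annotations(bundle.annotations_human, directory / f["annotations_human"])
    _write_annotations(bundle.annotations_mouse, directory / f["annotations_mouse"])

    ortho = bundle.orthologs.copy()
    for c in ("best_forward", "best_reverse"):
        ortho[c] = ortho[c].astype(int)
    ortho.to_csv(directory / f["orthologs"], sep="\t", index=False)

    bundle.phenotypes.to_csv(
        directory / f["phenotypes"], sep="\t", index=False, float_format="%.17g"
    )
    bundle.drug_targets.to_csv(directory / f["drug_targets"], sep="\t", index=False)

    pgx = bundle.pgx.copy()
    pgx["significant"] = pgx["significant"].astype(int)
    pgx.to_csv(directory / f["pgx"], sep="\t", index=False)

    bundle.network.to_csv(
        directory / f["network"], sep="\t", index=False, float_format="%.17g"
    )
    (directory / f["actionable"]).write_text("\n".join(bundle.actionable) + "\n")
    bundle.labels.to_csv(directory / f["labels"], sep="\t", index=False)
    bundle.xmap.to_csv(directory / f["xmap"], sep="\t", index=False)
    if bundle.truth is not None:
        bundle.truth.to_csv(directory / "truth.tsv", sep="\t", index=False)


def bundles_equal(a: ResourceBundle, b: ResourceBundle) -> bool:
    """Table-by-table equality; used by round-trip tests."""

    def ann_eq(x, y):
        return x == y

    frames = [
        (a.orthologs, b.orthologs),
        (a.phenotypes, b.phenotypes),
        (a.drug_targets, b.drug_targets),
        (a.pgx, b.pgx),
        (a.network, b.network),
        (a.labels, b.labels),
        (a.xmap, b.xmap),
    ]
    return (
        a.universe.equals(b.universe)
        and a.candidates == b.candidates
        and a.expression.equals(b.expression)
        and a.ontology_human.equals(b.ontology_human)
        and a.ontology_mouse.equals(b.ontology_mouse)
        and a.ontology_mp.equals(b.ontology_mp)
        and ann_eq(a.annotations_human, b.annotations_human)
        and ann_eq(a.annotations_mouse, b.annotations_mouse)
        and a.actionable == b.actionable
        and all(x.reset_index(drop=True).equals(y.reset_index(drop=True)) for x, y in frames)
    )
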