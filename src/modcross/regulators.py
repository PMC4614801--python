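"""Pivot regulator identification.

A transcription factor or miRNA is a pivot for a significant crosstalk
module pair when it regulates more than 2 genes in each module of the pair
and, per module, its targets are significantly enriched (upper-tail
hypergeometric p < 0.05 against a background gene universe — by default the
node set of the filtered interaction network).  TFs and miRNAs run through
identical logic and differ only in their type label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from scipy.stats import hypergeom

from .crosstalk import CrosstalkResult
from .mcode import GeneModule

logger = logging.getLogger(__name__)

TF = "TF"
MIRNA = "miRNA"
DEFAULT_MIN_TARGETS = 3  # "more than 2" regulations per module
DEFAULT_ALPHA = 0.05


@dataclass
class RegulatorTargetMap:
    """Bipartite regulator -> target-gene map with type labels."""

    entries: dict[str, tuple[str, set[str]]] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def add(self, regulator: str, rtype: str, targets: Iterable[str], source: str = "") -> None:
        if rtype not in (TF, MIRNA):
            raise ValueError(f"unknown regulator type {rtype!r}")
        if regulator in self.entries:
            old_type, old_targets = self.entries[regulator]
            if old_type != rtype:
                raise ValueError(f"{regulator}: conflicting types {old_type}/{rtype}")
            old_targets.update(targets)
        else:
            self.entries[regulator] = (rtype, set(targets))
        if source:
            self.provenance[regulator] = source

    def targets(self, regulator: str) -> set[str]:
        return self.entries[regulator][1]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class PivotResult:
    """Verdict for one (regulator, significant module pair) combination."""

    regulator: str
    type: str
    pair: tuple[tuple[str, int], tuple[str, int]]
    targets_in_module: tuple[int, int]
    p_hyper: tuple[float, float]
    is_pivot: bool


def read_regulator_map(
    paths: Sequence[str | Path],
    type_labels: Sequence[str],
) -> RegulatorTargetMap:
    """Union of 2/3-column (regulator, target[, source]) tables.

    Each file carries one regulator type; duplicate (regulator, target)
    pairs collapse.  A third column in the generator's dialect may instead
    hold the type label itself; it is honored when it matches TF/miRNA.
    """
    if len(paths) != len(type_labels):
        raise ValueError("one type label per file required")
    rmap = RegulatorTargetMap()
    for path, rtype in zip(paths, type_labels):
        path = Path(path)
        n_pairs = 0
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) == 2:
                    reg, target = fields
                    row_type, source = rtype, path.name
                elif len(fields) == 3:
                    reg, second, third = fields
                    if second in (TF, MIRNA):  # generator dialect: reg, type, target
                        row_type, target, source = second, third, path.name
                    else:
                        target, row_type, source = second, rtype, fields[2]
                else:
                    raise ValueError(
                        f"{path}:{lineno}: expected 2 or 3 fields, got {len(fields)}"
                    )
                rmap.add(reg, row_type, [target], source)
                n_pairs += 1
        if n_pairs == 0:
            logger.warning("%s: empty regulator file", path)
        else:
            logger.info("%s: %d regulator-target pairs", path, n_pairs)
    return rmap


def hypergeometric_enrichment(
    target_set: set[str], module_members: set[str], background: set[str]
) -> float:
    """Upper-tail P(X >= overlap) of the target/module overlap.

    Population = |background|, successes = |module_members|, draws =
    |targets restricted to background|.
    """
    if not background:
        raise ValueError("empty background universe")
    if not module_members <= background:
        raise ValueError("module members must lie inside the background")
    draws = target_set & background
    k = len(draws & module_members)
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, len(background), len(module_members), len(draws)))


def find_pivots(
    rmap: RegulatorTargetMap,
    significant_pairs: Sequence[CrosstalkResult],
    modules: Sequence[GeneModule],
    background: set[str],
    min_targets: int = DEFAULT_MIN_TARGETS,
    alpha: float = DEFAULT_ALPHA,
) -> list[PivotResult]:
    """Evaluate every regulator against every significant pair.

    All combinations are returned with verdicts; ``is_pivot`` requires, in
    BOTH modules of the pair, at least ``min_targets`` in-module targets
    (default 3, the strict reading of "more than 2") and hypergeometric
    p < ``alpha``.
    """
    if not significant_pairs:
        raise ValueError("no significant crosstalk pairs supplied")
    by_id = {m.module_id: m for m in modules}
    results = []
    for regulator in sorted(rmap.entries):
        rtype, targets = rmap.entries[regulator]
        targets_bg = targets & background
        for pair_result in significant_pairs:
            mods = [by_id[mid] for mid in pair_result.pair]
            counts = tuple(len(targets_bg & set(m.members)) for m in mods)
            ps = tuple(
                hypergeometric_enrichment(targets, set(m.members) & background, background)
                for m in mods
            )
            verdict = all(c >= min_targets for c in counts) and all(p < alpha for p in ps)
            results.append(
                PivotResult(
                    regulator=regulator,
                    type=rtype,
                    pair=pair_result.pair,
                    targets_in_module=counts,  # type: ignore[arg-type]
                    p_hyper=ps,  # type: ignore[arg-type]
                    is_pivot=verdict,
                )
            )
    return results


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def write_pivot_table(path, results: Iterable[PivotResult]) -> None:
    with open(path, "w") as fh:
        fh.write(
            "regulator\ttype\tinflammation_module\tcancer_module\t"
            "targets_inflammation\ttargets_cancer\tp_inflammation\tp_cancer\tpivot\n"
        )
        for r in results:
            fh.write(
                f"{r.regulator}\t{r.type}\t"
                f"{r.pair[0][0]}:{r.pair[0][1]}\t{r.pair[1][0]}:{r.pair[1][1]}\t"
                f"{r.targets_in_module[0]}\t{r.targets_in_module[1]}\t"
                f"{r.p_hyper[0]:.6g}\t{r.p_hyper[1]:.6g}\t{int(r.is_pivot)}\n"
            )


def pivot_layer_graph(
    pivots: Iterable[PivotResult],
    rmap: RegulatorTargetMap,
    modules: Sequence[GeneModule],
    net,
):
    """Two-layer graph: pivot regulators on top, module subnetwork below."""
    import networkx as nx

    by_id = {m.module_id: m for m in modules}
    out = nx.Graph()
    seen_pairs = set()
    for r in pivots:
        if not r.is_pivot:
            continue
        out.add_node(r.regulator, layer="regulator", regulator_type=r.type)
        for mid in r.pair:
            mod = by_id[mid]
            if mid not in seen_pairs:
                seen_pairs.add(mid)
                for u in sorted(mod.members):
                    out.add_node(u, layer="module", context=mod.context)
                    if u in net:
                        for v in sorted(net[u]):
                            if v in mod.members:
                                out.add_edge(u, v, kind="ppi")
            for g in sorted(rmap.targets(r.regulator) & set(mod.members)):
                out.add_edge(r.regulator, g, kind="regulation")
    return out
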