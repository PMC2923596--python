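"""Readers and writers for interaction networks.

Two plain-text inputs are supported: whitespace/tab separated edge lists
(one interaction per line, ``#``/``!`` comments, single-token lines declare
isolated nodes) and a minimal PSI-MI TAB (MITAB) subset that uses only the
interactor-A/interactor-B identifier columns.  Raw records are normalised
into a clean undirected simple graph: bait-prey orientation is discarded,
duplicate records (either orientation) collapse to one edge, and
self-interactions are dropped with a counted warning.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

from .network import InteractionNetwork

__all__ = ["ParseReport", "read_edge_list", "read_mitab", "write_edge_list"]

logger = logging.getLogger(__name__)

_COMMENT_PREFIXES = ("#", "!")


@dataclass
class ParseReport:
    """Bookkeeping for one parsed interaction file."""

    records: int = 0
    self_loops_dropped: int = 0
    duplicates_collapsed: int = 0
    malformed_skipped: int = 0
    isolated_declared: int = 0


def _build(pairs, singles, report: ParseReport, source: str) -> InteractionNetwork:
    if report.records == 0 and report.isolated_declared == 0:
        raise ValueError(f"{source}: zero parsable records")
    net = InteractionNetwork.from_pairs(pairs, extra_nodes=singles)
    report.duplicates_collapsed = (
        report.records - report.self_loops_dropped - net.E
    )
    if report.self_loops_dropped:
        logger.warning(
            "%s: dropped %d self-interaction record(s)", source, report.self_loops_dropped
        )
    if report.duplicates_collapsed:
        logger.info(
            "%s: collapsed %d duplicate record(s)", source, report.duplicates_collapsed
        )
    return net


def read_edge_list(
    path: str | os.PathLike,
    strict: bool = False,
    with_report: bool = False,
):
    """Read a two-column edge list into an :class:`InteractionNetwork`.

    Parameters
    ----------
    path:
        Text file, one interaction per line, two whitespace/tab separated
        node identifiers.  Lines starting with ``#`` or ``!`` are skipped.
        A line with a single token declares an isolated node.
    strict:
        If true, any line with a single token or other surprises raises
        instead of being treated leniently.
    with_report:
        Also return the :class:`ParseReport`.
    """
    pairs: list[tuple[str, str]] = []
    singles: list[str] = []
    report = ParseReport()
    with open(path, "rt", encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(_COMMENT_PREFIXES):
                continue
            fields = stripped.split()
            if len(fields) == 1:
                if strict:
                    raise ValueError(f"{path}:{lineno}: expected two fields, got one")
                singles.append(fields[0])
                report.isolated_declared += 1
                continue
            a, b = fields[0].strip(), fields[1].strip()
            report.records += 1
            if a == b:
                report.self_loops_dropped += 1
                singles.append(a)
                continue
            pairs.append((a, b))
    net = _build(pairs, singles, report, str(path))
    return (net, report) if with_report else net


def read_mitab(
    path: str | os.PathLike,
    strict: bool = False,
    with_report: bool = False,
):
    """Read the interactor-A/B columns of a PSI-MI TAB file.

    Only columns 1-2 (the interactor identifiers) are used; every other
    MITAB column is ignored.  Identifiers are kept verbatim after
    whitespace trimming — no accession mapping is attempted.
    """
    pairs: list[tuple[str, str]] = []
    singles: list[str] = []
    report = ParseReport()
    with open(path, "rt", encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.rstrip("\n")
            if not stripped.strip() or stripped.startswith(_COMMENT_PREFIXES):
                continue
            fields = stripped.split("\t")
            if len(fields) < 2:
                if strict:
                    raise ValueError(f"{path}:{lineno}: fewer than 2 tab-separated columns")
                report.malformed_skipped += 1
                logger.warning("%s:%d: skipping record with < 2 columns", path, lineno)
                continue
            a, b = fields[0].strip(), fields[1].strip()
            if not a or not b:
                report.malformed_skipped += 1
                continue
            report.records += 1
            if a == b:
                report.self_loops_dropped += 1
                singles.append(a)
                continue
            pairs.append((a, b))
    net = _build(pairs, singles, report, str(path))
    return (net, report) if with_report else net


def write_edge_list(net: InteractionNetwork, path: str | os.PathLike) -> None:
    """Write a network as a tab-separated edge list.

    Isolated nodes are written as single-token lines so the round trip
    ``read_edge_list(write_edge_list(net))`` reproduces both the node set
    and the edge set exactly.
    """
    deg = net.degree_sequence()
    with open(path, "wt", encoding="utf-8") as handle:
        handle.write("# ppinet edge list\n")
        for a, b in net.edge_names():
            handle.write(f"{a}\t{b}\n")
        for i, name in enumerate(net.node_ids):
            if deg[i] == 0:
                handle.write(f"{name}\n")
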