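"""End-to-end orchestration of the three analyses from one config.

``run_network_analysis`` scores all protein pairs and summarizes the
functional similarity networks for every score kind and threshold;
``run_ppi_analysis`` reports interaction-annotation enrichment,
significant centroid subnetworks and their before/after term
overrepresentation; ``run_window_analysis`` scans gene coordinates for
functionally coherent windows and the annotation gain from predicted
terms.  Each run is reproducible from the config and seed; every output
carries the config hash.
"""

from __future__ import annotations

import hashlib
import io
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import enrichment, genome_windows, ppi, semsim, simnet
from .ontology import AnnotationCorpus, compute_ic, parse_obo, read_gaf

__all__ = ["RunConfig", "Pipeline", "load_config"]

logger = logging.getLogger("funsimnet")


@dataclass
class RunConfig:
    """Input paths, thresholds and seeds for one pipeline run."""

    obo: str
    gaf: str
    predicted_gaf: str | None = None
    ppi: str | None = None
    loci: str | None = None
    hits: str | None = None
    out_dir: str = "out"
    network_thresholds: tuple[float, ...] = simnet.DEFAULT_THRESHOLDS
    window_size: int = 15_000
    window_go_threshold: float = genome_windows.GO_THRESHOLD
    window_funsim_threshold: float = genome_windows.FUNSIM_THRESHOLD
    alpha: float = 0.05
    prediction_confidence: float = 0.8
    n_randomizations: int = 100
    seed: int = 0
    mode: str = "schlicker"
    combiner: str = "max"

    def __post_init__(self):
        for name in ("network_thresholds",):
            values = getattr(self, name)
            if any(not 0.0 <= t <= 1.0 for t in values):
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def config_hash(self) -> str:
        digest = hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode())
        return digest.hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML mapping of RunConfig fields."""
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    if "network_thresholds" in raw:
        raw["network_thresholds"] = tuple(raw["network_thresholds"])
    return RunConfig(**raw)


def _read_predicted(path: str, dag, cutoff: float) -> AnnotationCorpus:
    """Predicted annotations: GAF-style with an optional trailing
    confidence column; rows below the confidence cutoff are dropped."""
    pairs = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            fields = line.split("\t")
            confidence = 1.0
            if len(fields) >= 3:
                try:
                    confidence = float(fields[2])
                except ValueError:
                    pass
            if confidence >= cutoff:
                pairs.append((fields[0], fields[1]))
    return AnnotationCorpus.from_pairs(dag, pairs)


class Pipeline:
    """Shared loading and the three analysis stages."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.out_dir = Path(config.out_dir)
        start = time.perf_counter()
        with open(config.obo) as handle:
            self.dag = parse_obo(handle)
        with open(config.gaf) as handle:
            self.known = AnnotationCorpus.from_pairs(
                self.dag, read_gaf(handle))
        self.predicted = None
        if config.predicted_gaf:
            self.predicted = _read_predicted(
                config.predicted_gaf, self.dag, config.prediction_confidence)
        logger.info("loaded ontology (%d terms) and corpus (%d proteins) "
                    "in %.2f s", len(self.dag.terms), len(self.known.proteins),
                    time.perf_counter() - start)
        self._pairs: pd.DataFrame | None = None

    # -- shared -------------------------------------------------------------

    def corpus(self, state: str = "known") -> AnnotationCorpus:
        if state == "known" or self.predicted is None:
            return self.known
        return self.known.merged_with(self.predicted)

    def pair_scores(self, proteins=None, state: str = "known",
                    ) -> pd.DataFrame:
        corpus = self.corpus(state)
        if proteins is not None:
            corpus = corpus.restricted_to(proteins)
        ic = compute_ic(self.dag, corpus, require_all_namespaces=False)
        return semsim.all_pairs_scores(
            corpus, self.dag, ic,
            mode=self.config.mode, combiner=self.config.combiner)

    def _write(self, relative: str, writer) -> Path:
        path = self.out_dir / relative
        path.parent.mkdir(parents=True, exist_ok=True)
        writer(path)
        return path

    def _stamp(self, payload: dict) -> dict:
        payload["config_hash"] = self.config.config_hash
        return payload

    # -- analyses -----------------------------------------------------------

    def run_network_analysis(self) -> dict[str, simnet.TopologySummary]:
        """Topology summaries for every score kind at every threshold."""
        start = time.perf_counter()
        pairs = self.pair_scores()
        self._write("networks/pairs.tsv",
                    lambda p: semsim.write_pairs(pairs, p))
        summaries: dict[str, simnet.TopologySummary] = {}
        for kind in simnet.SCORE_KINDS:
            for threshold in self.config.network_thresholds:
                net = simnet.build_network(pairs, kind, threshold)
                summary = simnet.network_summary(net)
                key = f"{kind}@{threshold:g}"
                summaries[key] = summary
                stem = f"networks/{kind}_{threshold:g}"
                self._write(f"{stem}.edges.tsv",
                            lambda p, n=net: simnet.write_edge_list(n, p))
                payload = self._stamp(json.loads(summary.to_json()))
                self._write(f"{stem}.summary.json",
                            lambda p, d=payload: Path(p).write_text(
                                json.dumps(d, indent=2)))
                logger.info("network %s: %d nodes / %d edges", key,
                            summary.n_nodes, summary.n_edges)
        logger.info("network analysis done in %.2f s",
                    time.perf_counter() - start)
        return summaries

    def run_ppi_analysis(self) -> dict:
        """Enrichment accounting, subnetwork significance, and per-
        subnetwork overrepresentation under both annotation states."""
        if not self.config.ppi:
            raise ValueError("config has no PPI path")
        start = time.perf_counter()
        with open(self.config.ppi) as handle:
            network = ppi.read_ppi(handle)
        status = ppi.interaction_annotation_status(
            network, self.known, self.predicted)
        significances = ppi.significant_subnetworks(
            network, n_randomizations=self.config.n_randomizations,
            seed=self.config.seed, alpha=self.config.alpha)
        significant = [s for s in significances if s.significant]

        subnet_rows = []
        members_of = {s.centroid: s for s in ppi.centroid_subnetworks(network)}
        per_subnetwork = {}
        for result in significances:
            subnet_rows.append((
                result.centroid, members_of[result.centroid].n_i,
                members_of[result.centroid].g_i, result.c_i, result.nu,
                result.t, result.p_value, result.significant))
        for result in significant:
            members = members_of[result.centroid].members
            before = enrichment.overrepresented_terms(
                members, self.known, alpha=self.config.alpha)
            after = enrichment.overrepresented_terms(
                members, self.corpus("known+predicted"),
                alpha=self.config.alpha)
            per_subnetwork[result.centroid] = {
                "before": before,
                "after": after,
                "gain": enrichment.annotation_gain(before, after),
            }
        frame = pd.DataFrame(subnet_rows, columns=[
            "centroid", "n_i", "g_i", "c_i", "nu", "t", "p", "significant"])
        self._write("ppi/subnetworks.tsv",
                    lambda p: frame.to_csv(p, sep="\t", index=False,
                                           float_format="%.6g"))
        self._write("ppi/annotation_status.json",
                    lambda p: Path(p).write_text(json.dumps(
                        self._stamp({"status": status}), indent=2)))
        logger.info("ppi analysis: %d/%d subnetworks significant, %.2f s",
                    len(significant), len(significances),
                    time.perf_counter() - start)
        return {"status": status, "significance": significances,
                "per_subnetwork": per_subnetwork}

    def run_window_analysis(self) -> dict:
        """Sliding-window scan plus before/after overrepresentation and
        the annotation-gain split for selected windows."""
        if not self.config.loci:
            raise ValueError("config has no loci path")
        start = time.perf_counter()
        with open(self.config.loci) as handle:
            loci = genome_windows.read_loci(handle)
        gene_ids = [g.protein for g in loci]
        pairs = self.pair_scores(proteins=gene_ids,
                                 state="known+predicted"
                                 if self.predicted else "known")
        results: list[genome_windows.WindowResult] = []
        for strand_mode in ("plus", "minus", "both"):
            spec = genome_windows.WindowSpec(size=self.config.window_size,
                                             strand_mode=strand_mode)
            results.extend(genome_windows.scan_genome(
                loci, pairs, spec,
                go_threshold=self.config.window_go_threshold,
                funsim_threshold=self.config.window_funsim_threshold))
        selected = [r for r in results if r.selected]

        gains, n_previously_unannotated = [], 0
        per_window = {}
        merged = self.corpus("known+predicted")
        for result in selected:
            members = result.member_proteins
            before = enrichment.overrepresented_terms(
                members, self.known, alpha=self.config.alpha)
            after = enrichment.overrepresented_terms(
                members, merged, alpha=self.config.alpha)
            gain = enrichment.annotation_gain(before, after)
            key = (result.window.chromosome, result.window.start,
                   result.window.strand_mode)
            per_window[key] = {"before": before, "after": after,
                               "gain": gain}
            if gain.previously_unannotated:
                n_previously_unannotated += 1
            elif gain.gain_percent is not None:
                gains.append(gain.gain_percent)
        self._write("windows/windows.tsv",
                    lambda p: genome_windows.write_windows(results, p))
        summary = self._stamp({
            "n_windows": len(results),
            "n_selected": len(selected),
            "n_previously_unannotated": n_previously_unannotated,
            "mean_gain_percent":
                float(pd.Series(gains).mean()) if gains else None,
        })
        self._write("windows/summary.json",
                    lambda p: Path(p).write_text(json.dumps(summary,
                                                            indent=2)))
        logger.info("window analysis: %d/%d selected, %.2f s",
                    len(selected), len(results),
                    time.perf_counter() - start)
        return {"results": results, "selected": selected,
                "per_window": per_window, "summary": summary}
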