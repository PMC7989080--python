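"""End-to-end workflows wiring the modules together, with run manifests.

Two workflows cover the typical use of the package:

* **select** — preprocess a matrix, compute the entropy profile, select
  related bits at each requested reduced level z, and emit the reduced
  matrices plus the fraction of bits retained per z.
* **impact** — for one selection, compare the full-set and reduced-set
  Tanimoto scores over all distinct pairs: per-pair deltas, the fraction of
  pairs whose |delta| exceeds user thresholds, the top-K pairs by |delta|,
  and the sign test on those top pairs' deltas.

Every run writes a JSON manifest (inputs hashed, parameters, seed, package
version) sufficient to reproduce the outputs exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .entropy import (
    EntropyProfile,
    RelatednessSelection,
    entropy_profile,
    reduce_matrix,
    select_related,
)
from .matrix import FingerprintMatrix
from .nulls import sign_test
from .preprocess import FilterReport, apply_filters
from .similarity import similarity_matrix

__all__ = ["RunConfig", "SelectResult", "ImpactResult", "run_select_workflow", "run_impact_workflow"]


@dataclass
class RunConfig:
    """Parameters of one run, echoed verbatim into the manifest."""

    matrix_path: str | None = None
    scheme: str = "unknown"
    z_values: list[float] = field(default_factory=lambda: [0.1, 0.2, 0.3])
    epsilon: float = 1e-10
    null_draws: int = 10_000
    seed: int = 0
    out_dir: str | None = None
    max_off_fraction: float = 0.9
    delta_thresholds: list[float] = field(default_factory=lambda: [0.05, 0.1, 0.2])
    top_k: int = 30

    def manifest(self, extra: dict | None = None) -> dict:
        doc = {
            "fpentropy_version": __version__,
            "matrix_path": self.matrix_path,
            "matrix_sha256": _sha256(self.matrix_path),
            "scheme": self.scheme,
            "z_values": self.z_values,
            "epsilon": self.epsilon,
            "null_draws": self.null_draws,
            "seed": self.seed,
            "max_off_fraction": self.max_off_fraction,
            "delta_thresholds": self.delta_thresholds,
            "top_k": self.top_k,
        }
        doc.update(extra or {})
        return doc


def _sha256(path: str | None) -> str | None:
    if path is None or not Path(path).is_file():
        return None
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class SelectResult:
    filtered: FingerprintMatrix
    filter_report: FilterReport
    profile: EntropyProfile
    selections: dict[float, RelatednessSelection]
    reduced: dict[float, FingerprintMatrix]
    fraction_retained: dict[float, float]


def run_select_workflow(
    M: FingerprintMatrix, cfg: RunConfig, skip_filters: bool = False
) -> SelectResult:
    """preprocess -> entropy profile -> per-z selection -> reduced matrices."""
    if skip_filters:
        filtered, report = M, FilterReport(n_input_rows=M.n_compounds)
    else:
        filtered, report = apply_filters(M, cfg.max_off_fraction)
    profile = entropy_profile(filtered)
    selections: dict[float, RelatednessSelection] = {}
    reduced: dict[float, FingerprintMatrix] = {}
    fraction: dict[float, float] = {}
    for z in cfg.z_values:
        sel = select_related(profile, z)
        selections[z] = sel
        fraction[z] = sel.fraction_retained
        if sel.reduced_indices:
            reduced[z] = reduce_matrix(filtered, sel)
    return SelectResult(filtered, report, profile, selections, reduced, fraction)


@dataclass
class ImpactResult:
    z: float
    deltas: np.ndarray  # reduced minus full score per distinct pair
    pair_index: list[tuple[str, str]]
    fraction_exceeding: dict[float, float]
    top_pairs: list[tuple[str, str, float]]  # signed delta of the top-|delta| pairs
    sign_test_p: float


def run_impact_workflow(
    M: FingerprintMatrix, selection: RelatednessSelection, cfg: RunConfig
) -> ImpactResult:
    """Pairwise score deltas between full and reduced bit sets, plus the
    sign test over the top-K most affected pairs."""
    if not selection.related_indices:
        m = M.n_compounds
        pairs = [
            (M.compound_ids[a], M.compound_ids[b])
            for a in range(m)
            for b in range(a + 1, m)
        ]
        zeros = np.zeros(len(pairs))
        return ImpactResult(
            z=selection.z,
            deltas=zeros,
            pair_index=pairs,
            fraction_exceeding={t: 0.0 for t in cfg.delta_thresholds},
            top_pairs=[(a, b, 0.0) for a, b in pairs[: cfg.top_k]],
            sign_test_p=1.0,
        )

    reduced = reduce_matrix(M, selection)
    S_full = similarity_matrix(M)
    S_red = similarity_matrix(reduced)
    iu = np.triu_indices(M.n_compounds, k=1)
    deltas = (S_red - S_full)[iu]
    pairs = [(M.compound_ids[a], M.compound_ids[b]) for a, b in zip(*iu)]
    absd = np.abs(deltas)
    frac = {t: float((absd > t).mean()) for t in cfg.delta_thresholds}
    order = np.argsort(-absd, kind="stable")[: cfg.top_k]
    top = [(pairs[i][0], pairs[i][1], float(deltas[i])) for i in order]
    p = sign_test([d for _, _, d in top]) if top else 1.0
    return ImpactResult(
        z=selection.z,
        deltas=deltas,
        pair_index=pairs,
        fraction_exceeding=frac,
        top_pairs=top,
        sign_test_p=p,
    )


def write_manifest(cfg: RunConfig, out_dir: str | Path, extra: dict | None = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(cfg.manifest(extra), indent=2, sort_keys=True) + "\n")
    return path
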