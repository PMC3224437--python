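"""Synthetic metabolite panels with known ground-truth association structure.

The generator emulates the shape of a targeted serum metabolomics panel
(amino acids, a hexose, acyl-carnitines, phosphatidylcholine species and
sphingomyelins measured over ~1000 fasting samples): log-scale
concentrations drawn from a multivariate normal whose precision matrix has
within-class chain structure with a configurable partial-correlation
strength, so the true conditional-dependence graph is known exactly.
Alternatively the panel can be stitched from kinetic reaction-chain
simulations per class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import (
    ConcentrationEnsemble,
    Reaction,
    ReactionNetwork,
    simulate_ensemble,
)
from .lipids import parse_metabolite_name

__all__ = ["PanelSpec", "default_panel_spec", "generate_synthetic_panel"]


@dataclass
class PanelSpec:
    """Named metabolite classes with their member ids."""

    classes: dict[str, list[str]]

    def __post_init__(self) -> None:
        ids = self.metabolite_ids
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate metabolite ids in panel spec")
        for mid in ids:
            parse_metabolite_name(mid)  # every id must follow the nomenclature

    @property
    def metabolite_ids(self) -> list[str]:
        return [mid for members in self.classes.values() for mid in members]

    @property
    def class_map(self) -> dict[str, str]:
        return {mid: cls for cls, members in self.classes.items() for mid in members}

    @property
    def total(self) -> int:
        return len(self.metabolite_ids)


def _carn(c: int, d: int, variant: str | None = None) -> str:
    return f"C{c}:{d}-{variant}-carn" if variant else f"C{c}:{d}-carn"


def default_panel_spec() -> PanelSpec:
    """A serum-panel-like composition: 14 amino acids, 1 hexose, 38
    acyl-carnitines, 36 diacyl-PCs, 38 acyl-alkyl-PCs, 13 lyso-PCs, 9
    sphingomyelins and 5 hydroxy-sphingomyelins (154 metabolites)."""
    amino = ["Arg", "Gln", "Gly", "His", "Met", "Orn", "Phe", "Pro",
             "Ser", "Thr", "Trp", "Tyr", "Val", "xLeu"]
    carn = (
        [_carn(c, 0) for c in (2, 3, 4, 5, 6, 8, 10, 12, 14, 16, 18)]
        + [_carn(c, 1) for c in (8, 10, 12, 14, 16, 18)]
        + [_carn(c, 2) for c in (10, 12, 14, 16, 18)]
        + [_carn(5, 1)]
        + [_carn(c, d, "OH") for c, d in
           ((10, 0), (12, 0), (14, 0), (16, 0), (16, 1), (18, 0), (18, 1))]
        + [_carn(c, 0, "DC") for c in (4, 6, 8, 10, 12, 14)]
        + [_carn(c, 0, "M-DC") for c in (4, 6)]
    )
    pc_aa = [f"PC aa C{c}:{d}" for c, d in (
        (28, 1), (30, 0), (30, 2), (32, 0), (32, 1), (32, 2), (32, 3),
        (34, 1), (34, 2), (34, 3), (34, 4), (36, 0), (36, 1), (36, 2),
        (36, 3), (36, 4), (36, 5), (36, 6), (38, 0), (38, 3), (38, 4),
        (38, 5), (38, 6), (40, 2), (40, 3), (40, 4), (40, 5), (40, 6),
        (42, 0), (42, 1), (42, 2), (42, 4), (42, 5), (42, 6), (44, 5), (44, 6),
    )]
    pc_ae = [f"PC ae C{c}:{d}" for c, d in (
        (30, 0), (30, 1), (30, 2), (32, 1), (32, 2), (34, 0), (34, 1),
        (34, 2), (34, 3), (36, 0), (36, 1), (36, 2), (36, 3), (36, 4),
        (36, 5), (38, 0), (38, 1), (38, 2), (38, 3), (38, 4), (38, 5),
        (38, 6), (40, 1), (40, 2), (40, 3), (40, 4), (40, 5), (40, 6),
        (42, 1), (42, 2), (42, 3), (42, 4), (42, 5), (44, 3), (44, 4),
        (44, 5), (44, 6), (30, 6),
    )]
    lyso = [f"lysoPC a C{c}:{d}" for c, d in (
        (14, 0), (16, 0), (16, 1), (18, 0), (18, 1), (18, 2), (20, 3),
        (20, 4), (24, 0), (26, 0), (26, 1), (28, 0), (28, 1),
    )]
    sm = [f"SM C{c}:{d}" for c, d in (
        (16, 0), (16, 1), (18, 0), (18, 1), (20, 2), (24, 0), (24, 1),
        (26, 0), (26, 1),
    )]
    sm_oh = [f"SM (OH) C{c}:{d}" for c, d in ((14, 1), (16, 1), (22, 1), (22, 2), (24, 1))]
    return PanelSpec(
        classes={
            "amino acid": amino,
            "hexose": ["H1"],
            "acyl-carnitine": carn,
            "diacyl-PC": pc_aa,
            "acyl-alkyl-PC": pc_ae,
            "lyso-PC": lyso,
            "sphingomyelin": sm,
            "hydroxy-sphingomyelin": sm_oh,
        }
    )


def _chain_precision(size: int, strength: float) -> np.ndarray:
    """Tridiagonal precision matrix whose adjacent partial correlations equal
    ``strength`` (requires |strength| < 0.5 for positive definiteness)."""
    omega = np.eye(size)
    for i in range(size - 1):
        omega[i, i + 1] = omega[i + 1, i] = -strength
    return omega


def generate_synthetic_panel(
    spec: PanelSpec | None = None,
    structure: str = "block_cov",
    n_samples: int = 1020,
    strength: float = 0.3,
    sigma: float = 0.2,
    seed: int | None = None,
) -> tuple[ConcentrationEnsemble, pd.DataFrame]:
    """Generate a synthetic log-concentration panel with known truth.

    ``block_cov`` draws from a multivariate normal whose precision matrix is
    block diagonal with a within-class chain of partial correlation
    ``strength``; ``simulator`` builds one reversible first-order reaction
    chain with exchange reactions per class and stitches the kinetic
    ensembles together (noise level ``sigma``).  Returns the ensemble and
    the boolean ground-truth adjacency of the generating structure.
    """
    spec = spec or default_panel_spec()
    ids = spec.metabolite_ids
    rng = np.random.default_rng(seed)
    truth = pd.DataFrame(False, index=ids, columns=ids)

    if structure == "block_cov":
        blocks = []
        for cls, members in spec.classes.items():
            k = len(members)
            omega = _chain_precision(k, strength)
            try:
                np.linalg.cholesky(omega)
            except np.linalg.LinAlgError as exc:
                raise ValueError(
                    f"requested precision block for class {cls!r} is not positive definite"
                ) from exc
            blocks.append(np.linalg.inv(omega))
            for a, b in zip(members, members[1:]):
                truth.loc[a, b] = truth.loc[b, a] = True
        m = spec.total
        X = np.empty((n_samples, m))
        col = 0
        for block in blocks:
            k = block.shape[0]
            L = np.linalg.cholesky(block)
            X[:, col : col + k] = rng.standard_normal((n_samples, k)) @ L.T
            col += k
        baseline = rng.normal(0.0, 1.0, size=m)  # per-metabolite log abundance
        data = pd.DataFrame(X + baseline, columns=ids)
    elif structure == "simulator":
        frames = []
        for cls, members in spec.classes.items():
            k = len(members)
            if k == 1:
                # isolated metabolite: log-normal noise only
                frames.append(
                    pd.DataFrame(rng.normal(0.0, sigma, size=(n_samples, 1)), columns=members)
                )
                continue
            net = _reversible_chain_with_exchange(k)
            ens = simulate_ensemble(
                net, sigma=sigma, n_samples=n_samples,
                seed=int(rng.integers(2**31 - 1)),
            )
            frame = ens.data.copy()
            frame.columns = members
            frames.append(frame)
            for a, b in zip(members, members[1:]):
                truth.loc[a, b] = truth.loc[b, a] = True
        data = pd.concat(frames, axis=1)[ids]
    else:
        raise ValueError("structure must be 'block_cov' or 'simulator'")

    return ConcentrationEnsemble(data=data, classes=spec.class_map), truth


def _reversible_chain_with_exchange(size: int) -> ReactionNetwork:
    """Reversible first-order chain M1 <-> ... <-> Mk, every metabolite with
    input and output exchange reactions (the well-identifiable regime)."""
    mets = [f"M{i}" for i in range(1, size + 1)]
    rx = []
    for a, b in zip(mets, mets[1:]):
        rx.append(Reaction(name=f"{a}{b}_f", educts={a: 1}, products={b: 1}, k=1.0))
        rx.append(Reaction(name=f"{a}{b}_b", educts={b: 1}, products={a: 1}, k=1.0))
    for met in mets:
        rx.append(Reaction(name=f"in_{met}", educts={}, products={met: 1}, k=1.0))
        rx.append(Reaction(name=f"out_{met}", educts={met: 1}, products={}, k=1.0))
    return ReactionNetwork(mets, rx)
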