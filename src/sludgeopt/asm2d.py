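"""ASM2d biokinetic model: 19 components, 21 processes, conservation-built
stoichiometry.

The Activated Sludge Model No. 2d (IWA) describes COD oxidation,
nitrification, denitrification and enhanced biological phosphorus removal
with 9 soluble and 10 particulate components.  The stoichiometric matrix is
assembled from the published "specified" coefficients, with the dependent
entries (SNH4, SPO4, SALK, XTSS and the electron acceptor) solved from the
elemental N / P / charge / solids / COD conservation equations, so the
continuity checks close to machine precision by construction.

Units: concentrations g·m^-3 (SALK: mol HCO3·m^-3), rates d^-1, volumes m^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "COMPONENTS",
    "SOLUBLE_INDEX",
    "PARTICULATE_INDEX",
    "IDX",
    "Asm2dState",
    "Param",
    "Asm2dParams",
    "ProcessMatrix",
    "stoichiometric_matrix",
    "continuity_residuals",
    "process_rates",
    "reactor_derivatives",
    "composite_variables",
]

COMPONENTS = (
    "SO2", "SF", "SA", "SNH4", "SNO3", "SPO4", "SI", "SALK", "SN2",
    "XI", "XS", "XH", "XPAO", "XPP", "XPHA", "XAUT", "XTSS", "XMeOH", "XMeP",
)
N_COMPONENTS = 19
IDX = {name: i for i, name in enumerate(COMPONENTS)}
SOLUBLE_INDEX = np.arange(0, 9)          # SO2 .. SN2 (9 dissolved compounds)
PARTICULATE_INDEX = np.arange(9, 19)

PROCESS_NAMES = (
    "aerobic_hydrolysis", "anoxic_hydrolysis", "anaerobic_hydrolysis",
    "growth_het_SF", "growth_het_SA", "anoxic_growth_het_SF",
    "anoxic_growth_het_SA", "fermentation", "lysis_het",
    "storage_PHA", "aerobic_storage_PP", "anoxic_storage_PP",
    "aerobic_growth_PAO", "anoxic_growth_PAO", "lysis_PAO",
    "lysis_PP", "lysis_PHA", "aerobic_growth_AUT", "lysis_AUT",
    "precipitation_P", "redissolution_P",
)
N_PROCESSES = 21

# COD per gram NO3-N / N2-N as electron acceptors
_COD_NO3 = -64.0 / 14.0
_COD_N2 = -24.0 / 14.0
# FePO4 and Fe(OH)3 grams per gram P precipitated
_G_MEP_PER_P = 150.8 / 31.0
_G_MEOH_PER_P = 106.87 / 31.0


class Asm2dState:
    """One completely mixed volume's 19-component concentration vector.

    Construct from keyword concentrations (missing ones default to 0) or an
    explicit array.  Values must be non-negative.  The soluble/particulate
    partition used by downstream units (e.g. the settler) is carried as an
    index array and may be overridden at construction.
    """

    __slots__ = ("values", "soluble_index")

    def __init__(self, values=None, soluble_index=None, **conc):
        if values is not None:
            arr = np.asarray(values, dtype=float).copy()
            if arr.shape != (N_COMPONENTS,):
                raise ValueError(f"state needs exactly {N_COMPONENTS} components")
        else:
            arr = np.zeros(N_COMPONENTS)
        for name, v in conc.items():
            if name not in IDX:
                raise KeyError(f"unknown component {name!r}")
            arr[IDX[name]] = float(v)
        if np.any(arr < 0):
            bad = [COMPONENTS[i] for i in np.flatnonzero(arr < 0)]
            raise ValueError(f"negative concentration(s): {', '.join(bad)}")
        self.values = arr
        self.soluble_index = (
            np.asarray(soluble_index, dtype=int) if soluble_index is not None else SOLUBLE_INDEX.copy()
        )

    def __getattr__(self, name):
        if name in IDX:
            return self.values[IDX[name]]
        raise AttributeError(name)

    def __repr__(self):  # pragma: no cover
        pairs = ", ".join(f"{n}={v:.3g}" for n, v in zip(COMPONENTS, self.values) if v)
        return f"Asm2dState({pairs})"

    def copy(self) -> "Asm2dState":
        return Asm2dState(values=self.values, soluble_index=self.soluble_index)


@dataclass
class Param:
    """One kinetic parameter: value with unit, admissible range and the
    factor applied per degree away from the 20 degC reference."""

    value: float
    unit: str = "-"
    low: float = 0.0
    high: float = np.inf
    theta: float = 1.0  # Arrhenius-type base, value(T) = value * theta**(T-20)

    def at(self, temperature: float) -> float:
        return self.value * self.theta ** (temperature - 20.0)


def _default_kinetics() -> dict[str, Param]:
    """The 42 ASM2d kinetic parameters at 20 degC (typical published values).

    Temperature bases follow the published 10/20 degC pairs where given.
    Ranges bracket the defaults (half to double; efficiency and saturation
    fractions capped at 1).
    """
    def p(v, unit="-", theta=1.0, low=None, high=None):
        return Param(v, unit, v * 0.5 if low is None else low, v * 2.0 if high is None else high, theta)

    t2 = 2.0 ** 0.1   # rate halves from 20 to 10 degC
    kin = {
        # hydrolysis
        "K_H": p(3.0, "d-1", theta=t2),
        "eta_NO3_hyd": p(0.6, "-", high=1.0),
        "eta_fe": p(0.4, "-", high=1.0),
        "K_O2_hyd": p(0.2, "gO2 m-3"),
        "K_NO3_hyd": p(0.5, "gN m-3"),
        "K_X": p(0.1, "gCOD/gCOD"),
        # heterotrophs
        "mu_H": p(6.0, "d-1", theta=t2),
        "q_fe": p(3.0, "d-1", theta=t2),
        "b_H": p(0.4, "d-1", theta=t2),
        "eta_NO3_H": p(0.8, "-", high=1.0),
        "K_O2_H": p(0.2, "gO2 m-3"),
        "K_F": p(4.0, "gCOD m-3"),
        "K_fe": p(4.0, "gCOD m-3"),
        "K_A_H": p(4.0, "gCOD m-3"),
        "K_NO3_H": p(0.5, "gN m-3"),
        "K_NH4_H": p(0.05, "gN m-3"),
        "K_P_H": p(0.01, "gP m-3"),
        "K_ALK_H": p(0.1, "mol m-3"),
        # phosphorus accumulating organisms
        "q_PHA": p(3.0, "d-1", theta=(3.0 / 2.0) ** 0.1),
        "q_PP": p(1.5, "d-1", theta=(1.5 / 1.0) ** 0.1),
        "mu_PAO": p(1.0, "d-1", theta=(1.0 / 0.67) ** 0.1),
        "eta_NO3_PAO": p(0.6, "-", high=1.0),
        "b_PAO": p(0.2, "d-1", theta=t2),
        "b_PP": p(0.2, "d-1", theta=t2),
        "b_PHA": p(0.2, "d-1", theta=t2),
        "K_O2_PAO": p(0.2, "gO2 m-3"),
        "K_NO3_PAO": p(0.5, "gN m-3"),
        "K_A_PAO": p(4.0, "gCOD m-3"),
        "K_NH4_PAO": p(0.05, "gN m-3"),
        "K_PS": p(0.2, "gP m-3"),
        "K_P_PAO": p(0.01, "gP m-3"),
        "K_ALK_PAO": p(0.1, "mol m-3"),
        "K_PP": p(0.01, "gP/gCOD"),
        "K_MAX": p(0.34, "gP/gCOD"),
        "K_IPP": p(0.02, "gP/gCOD"),
        "K_PHA": p(0.01, "gCOD/gCOD"),
        # autotrophs
        "mu_AUT": p(1.0, "d-1", theta=(1.0 / 0.35) ** 0.1),
        "b_AUT": p(0.15, "d-1", theta=(0.15 / 0.05) ** 0.1),
        "K_O2_AUT": p(0.5, "gO2 m-3"),
        "K_NH4_AUT": p(1.0, "gN m-3"),
        "K_ALK_AUT": p(0.5, "mol m-3"),
        "K_P_AUT": p(0.01, "gP m-3"),
    }
    assert len(kin) == 42
    return kin


@dataclass
class Asm2dParams:
    """Full ASM2d parameter set: 42 kinetic entries, stoichiometric yields
    and composition fractions, plus the (default-off) chemical P module."""

    kinetic: dict[str, Param] = field(default_factory=_default_kinetics)
    # yields and inert fractions
    f_SI: float = 0.0
    Y_H: float = 0.625
    f_XI: float = 0.10
    Y_PO4: float = 0.40
    Y_PHA: float = 0.20
    Y_PAO: float = 0.625
    Y_A: float = 0.24
    # N content, g N per g COD (or per g for XTSS bearers)
    i_N_SF: float = 0.03
    i_N_SI: float = 0.01
    i_N_XI: float = 0.02
    i_N_XS: float = 0.03
    i_N_BM: float = 0.07
    # P content
    i_P_SF: float = 0.01
    i_P_SI: float = 0.00
    i_P_XI: float = 0.01
    i_P_XS: float = 0.01
    i_P_BM: float = 0.02
    # TSS per unit component
    i_TSS_XI: float = 0.75
    i_TSS_XS: float = 0.75
    i_TSS_BM: float = 0.90
    i_TSS_XPP: float = 3.23
    i_TSS_XPHA: float = 0.60
    # chemical P precipitation (off for a purely biological A2O train)
    include_chemical_p: bool = False
    k_PRE: float = 1.0
    k_RED: float = 0.6
    K_ALK_PRE: float = 0.5

    def __post_init__(self):
        if len(self.kinetic) != 42:
            raise ValueError("expected exactly 42 kinetic parameters")
        for name, par in self.kinetic.items():
            if par.value < 0:
                raise ValueError(f"kinetic parameter {name} must be >= 0")
            if not par.low <= par.value <= par.high:
                raise ValueError(f"range of {name} does not bracket its value")

    # -- convenience -------------------------------------------------------
    def k(self, name: str, temperature: float = 20.0) -> float:
        try:
            return self.kinetic[name].at(temperature)
        except KeyError:
            raise KeyError(f"missing kinetic parameter {name!r}") from None

    def with_values(self, **updates: float) -> "Asm2dParams":
        """Copy with some kinetic parameter values replaced."""
        kin = {n: replace(p) for n, p in self.kinetic.items()}
        for name, v in updates.items():
            if name not in kin:
                raise KeyError(f"unknown kinetic parameter {name!r}")
            kin[name].value = float(v)
        return replace(self, kinetic=kin)

    # -- flat text serialization: name value unit min max ------------------
    def to_file(self, path: str | Path) -> None:
        lines = ["# name\tvalue\tunit\tmin\tmax"]
        for name, par in self.kinetic.items():
            lines.append(f"{name}\t{par.value:.10g}\t{par.unit}\t{par.low:.10g}\t{par.high:.10g}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "Asm2dParams":
        base = cls()
        kin = {n: replace(p) for n, p in base.kinetic.items()}
        for ln in Path(path).read_text().splitlines():
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            name, value, unit, low, high = ln.split("\t")
            if name not in kin:
                raise KeyError(f"unknown kinetic parameter {name!r}")
            kin[name] = Param(float(value), unit, float(low), float(high), kin[name].theta)
        return replace(base, kinetic=kin)

    # composition vectors used by the conservation solver ------------------
    def composition(self) -> dict[str, np.ndarray]:
        i_cod = np.zeros(N_COMPONENTS)
        for n in ("SF", "SA", "SI", "XI", "XS", "XH", "XPAO", "XPHA", "XAUT"):
            i_cod[IDX[n]] = 1.0
        i_cod[IDX["SO2"]] = -1.0
        i_cod[IDX["SNO3"]] = _COD_NO3
        i_cod[IDX["SN2"]] = _COD_N2

        i_n = np.zeros(N_COMPONENTS)
        i_n[IDX["SNH4"]] = i_n[IDX["SNO3"]] = i_n[IDX["SN2"]] = 1.0
        i_n[IDX["SF"]] = self.i_N_SF
        i_n[IDX["SI"]] = self.i_N_SI
        i_n[IDX["XI"]] = self.i_N_XI
        i_n[IDX["XS"]] = self.i_N_XS
        for n in ("XH", "XPAO", "XAUT"):
            i_n[IDX[n]] = self.i_N_BM

        i_p = np.zeros(N_COMPONENTS)
        i_p[IDX["SPO4"]] = i_p[IDX["XPP"]] = 1.0
        i_p[IDX["SF"]] = self.i_P_SF
        i_p[IDX["SI"]] = self.i_P_SI
        i_p[IDX["XI"]] = self.i_P_XI
        i_p[IDX["XS"]] = self.i_P_XS
        for n in ("XH", "XPAO", "XAUT"):
            i_p[IDX[n]] = self.i_P_BM
        i_p[IDX["XMeP"]] = 1.0 / _G_MEP_PER_P

        i_ch = np.zeros(N_COMPONENTS)
        i_ch[IDX["SNH4"]] = 1.0 / 14.0
        i_ch[IDX["SNO3"]] = -1.0 / 14.0
        i_ch[IDX["SA"]] = -1.0 / 64.0
        i_ch[IDX["SPO4"]] = -1.5 / 31.0
        i_ch[IDX["SALK"]] = -1.0

        i_tss = np.zeros(N_COMPONENTS)
        i_tss[IDX["XI"]] = self.i_TSS_XI
        i_tss[IDX["XS"]] = self.i_TSS_XS
        for n in ("XH", "XPAO", "XAUT"):
            i_tss[IDX[n]] = self.i_TSS_BM
        i_tss[IDX["XPP"]] = self.i_TSS_XPP
        i_tss[IDX["XPHA"]] = self.i_TSS_XPHA
        i_tss[IDX["XMeOH"]] = 1.0
        i_tss[IDX["XMeP"]] = 1.0
        i_tss[IDX["XTSS"]] = -1.0  # conservation slot
        return {"COD": i_cod, "N": i_n, "P": i_p, "charge": i_ch, "TSS": i_tss}


@dataclass
class ProcessMatrix:
    """Stoichiometric matrix (process x component) with process names."""

    names: tuple
    matrix: np.ndarray  # (21, 19)


def _specified_rows(p: Asm2dParams) -> list[tuple[dict[str, float], str]]:
    """Per process: explicitly specified coefficients + electron acceptor tag
    ('O2', 'NO3' or 'none'); the dependent slots come from conservation."""
    hyd = {"XS": -1.0, "SF": 1.0 - p.f_SI, "SI": p.f_SI}
    lysis_h = {"XH": -1.0, "XS": 1.0 - p.f_XI, "XI": p.f_XI}
    lysis_pao = {"XPAO": -1.0, "XS": 1.0 - p.f_XI, "XI": p.f_XI}
    lysis_aut = {"XAUT": -1.0, "XS": 1.0 - p.f_XI, "XI": p.f_XI}
    return [
        (dict(hyd), "none"),                                   # 1 aerobic hydrolysis
        (dict(hyd), "none"),                                   # 2 anoxic hydrolysis
        (dict(hyd), "none"),                                   # 3 anaerobic hydrolysis
        ({"SF": -1.0 / p.Y_H, "XH": 1.0}, "O2"),               # 4 growth on SF
        ({"SA": -1.0 / p.Y_H, "XH": 1.0}, "O2"),               # 5 growth on SA
        ({"SF": -1.0 / p.Y_H, "XH": 1.0}, "NO3"),              # 6 anoxic growth on SF
        ({"SA": -1.0 / p.Y_H, "XH": 1.0}, "NO3"),              # 7 anoxic growth on SA
        ({"SF": -1.0, "SA": 1.0}, "none"),                     # 8 fermentation
        (lysis_h, "none"),                                     # 9 lysis of XH
        ({"SA": -1.0, "XPHA": 1.0, "XPP": -p.Y_PO4}, "none"),  # 10 storage of XPHA
        ({"XPP": 1.0, "XPHA": -p.Y_PHA}, "O2"),                # 11 aerobic storage of XPP
        ({"XPP": 1.0, "XPHA": -p.Y_PHA}, "NO3"),               # 12 anoxic storage of XPP
        ({"XPAO": 1.0, "XPHA": -1.0 / p.Y_PAO}, "O2"),         # 13 aerobic growth of XPAO
        ({"XPAO": 1.0, "XPHA": -1.0 / p.Y_PAO}, "NO3"),        # 14 anoxic growth of XPAO
        (lysis_pao, "none"),                                   # 15 lysis of XPAO
        ({"XPP": -1.0}, "none"),                               # 16 lysis of XPP
        ({"XPHA": -1.0, "SA": 1.0}, "none"),                   # 17 lysis of XPHA
        ({"XAUT": 1.0, "SNO3": 1.0 / p.Y_A}, "O2"),            # 18 growth of XAUT
        (lysis_aut, "none"),                                   # 19 lysis of XAUT
        ({"XMeOH": -_G_MEOH_PER_P, "XMeP": _G_MEP_PER_P}, "none"),   # 20 precipitation
        ({"XMeOH": _G_MEOH_PER_P, "XMeP": -_G_MEP_PER_P}, "none"),   # 21 redissolution
    ]


def stoichiometric_matrix(params: Asm2dParams | None = None) -> ProcessMatrix:
    """Assemble the 21 x 19 matrix, closing every conservation equation.

    Solve order per process: N -> SNH4, P -> SPO4 (unless explicitly set),
    COD -> SO2 (aerobic) or an SNO3->SN2 swap (anoxic), charge -> SALK,
    solids -> XTSS.
    """
    p = params or Asm2dParams()
    comp = p.composition()
    M = np.zeros((N_PROCESSES, N_COMPONENTS))

    for k, (spec, acceptor) in enumerate(_specified_rows(p)):
        row = np.zeros(N_COMPONENTS)
        for name, v in spec.items():
            row[IDX[name]] = v
        # nitrogen balance -> SNH4
        row[IDX["SNH4"]] = 0.0
        row[IDX["SNH4"]] = -(row * comp["N"]).sum()
        # phosphorus balance -> SPO4
        row[IDX["SPO4"]] = 0.0
        row[IDX["SPO4"]] = -(row * comp["P"]).sum()
        # COD balance -> electron acceptor
        if acceptor == "O2":
            row[IDX["SO2"]] = 0.0
            cod = (row * comp["COD"]).sum()
            row[IDX["SO2"]] = cod  # i_COD(SO2) = -1
        elif acceptor == "NO3":
            row[IDX["SNO3"]] += 0.0
            cod = (row * comp["COD"]).sum()
            x = cod / (_COD_NO3 - _COD_N2)  # g NO3-N reduced to N2 per unit rate
            row[IDX["SNO3"]] += -x
            row[IDX["SN2"]] += x
        # charge balance -> SALK
        row[IDX["SALK"]] = 0.0
        row[IDX["SALK"]] = (row * comp["charge"]).sum()  # i_charge(SALK) = -1
        # solids balance -> XTSS
        row[IDX["XTSS"]] = 0.0
        row[IDX["XTSS"]] = (row * comp["TSS"]).sum()     # i_TSS(XTSS) = -1
        M[k] = row
    return ProcessMatrix(names=PROCESS_NAMES, matrix=M)


def continuity_residuals(pm: ProcessMatrix, params: Asm2dParams | None = None) -> dict[str, np.ndarray]:
    """Per-process COD/N/P/charge/TSS balance residuals (should be ~0)."""
    p = params or Asm2dParams()
    comp = p.composition()
    return {name: pm.matrix @ vec for name, vec in comp.items()}


# ---------------------------------------------------------------------------
# kinetics


def _monod(S, K):
    return S / (K + S)


def _ratio_monod(num, den_scale, K):
    """Saturation in a ratio num/den: (num/den)/(K + num/den) computed as
    num/(K*den + num) to stay finite as den -> 0."""
    den = K * den_scale + num
    return np.where(den > 0.0, num / np.where(den > 0.0, den, 1.0), 0.0)


def kinetic_values(params: Asm2dParams, temperature: float = 20.0) -> dict[str, float]:
    """All 42 kinetic parameters evaluated at a temperature (cacheable)."""
    return {name: par.at(temperature) for name, par in params.kinetic.items()}


def process_rates(
    state: "Asm2dState | np.ndarray",
    params: Asm2dParams | None = None,
    temperature: float = 20.0,
    kvals: dict[str, float] | None = None,
) -> np.ndarray:
    """ASM2d process rate vector(s), g COD (or component unit) m^-3 d^-1.

    Accepts one 19-vector or an (n, 19) matrix of reactor states and
    returns (21,) or (n, 21) accordingly.  Negative concentrations are
    rejected; all returned rates are finite and non-negative.  Passing a
    precomputed ``kvals`` (see :func:`kinetic_values`) skips the
    temperature correction in hot loops.
    """
    p = params or Asm2dParams()
    arr = state.values if isinstance(state, Asm2dState) else np.asarray(state, dtype=float)
    single = arr.ndim == 1
    S = np.atleast_2d(arr)
    if S.shape[1] != N_COMPONENTS:
        raise ValueError(f"state needs {N_COMPONENTS} components")
    if np.any(S < 0.0):
        raise ValueError("negative concentration in state")

    def c(name):
        return S[:, IDX[name]]

    kv = kvals if kvals is not None else kinetic_values(p, temperature)
    if len(kv) != 42:
        raise KeyError("incomplete kinetic parameter set")
    k = kv.__getitem__

    SO2, SF, SA = c("SO2"), c("SF"), c("SA")
    SNH4, SNO3, SPO4, SALK = c("SNH4"), c("SNO3"), c("SPO4"), c("SALK")
    XH, XS, XPAO, XPP, XPHA, XAUT = c("XH"), c("XS"), c("XPAO"), c("XPP"), c("XPHA"), c("XAUT")

    R = np.zeros((S.shape[0], N_PROCESSES))

    # hydrolysis
    sat_XS = _ratio_monod(XS, XH, k("K_X"))
    o2_on = _monod(SO2, k("K_O2_hyd"))
    o2_off = k("K_O2_hyd") / (k("K_O2_hyd") + SO2)
    no3_on_h = _monod(SNO3, k("K_NO3_hyd"))
    no3_off_h = k("K_NO3_hyd") / (k("K_NO3_hyd") + SNO3)
    R[:, 0] = k("K_H") * o2_on * sat_XS * XH
    R[:, 1] = k("K_H") * k("eta_NO3_hyd") * o2_off * no3_on_h * sat_XS * XH
    R[:, 2] = k("K_H") * k("eta_fe") * o2_off * no3_off_h * sat_XS * XH

    # heterotrophs
    o2H = _monod(SO2, k("K_O2_H"))
    o2H_off = k("K_O2_H") / (k("K_O2_H") + SO2)
    no3H = _monod(SNO3, k("K_NO3_H"))
    no3H_off = k("K_NO3_H") / (k("K_NO3_H") + SNO3)
    nutH = _monod(SNH4, k("K_NH4_H")) * _monod(SPO4, k("K_P_H")) * _monod(SALK, k("K_ALK_H"))
    tot_sub = SF + SA
    prefSF = np.where(tot_sub > 0.0, SF / np.where(tot_sub > 0.0, tot_sub, 1.0), 0.0)
    prefSA = np.where(tot_sub > 0.0, SA / np.where(tot_sub > 0.0, tot_sub, 1.0), 0.0)
    growF = _monod(SF, k("K_F")) * prefSF * nutH * XH
    growA = _monod(SA, k("K_A_H")) * prefSA * nutH * XH
    R[:, 3] = k("mu_H") * o2H * growF
    R[:, 4] = k("mu_H") * o2H * growA
    R[:, 5] = k("mu_H") * k("eta_NO3_H") * o2H_off * no3H * growF
    R[:, 6] = k("mu_H") * k("eta_NO3_H") * o2H_off * no3H * growA
    R[:, 7] = k("q_fe") * o2H_off * no3H_off * _monod(SF, k("K_fe")) * _monod(SALK, k("K_ALK_H")) * XH
    R[:, 8] = k("b_H") * XH

    # PAOs
    o2P = _monod(SO2, k("K_O2_PAO"))
    o2P_off = k("K_O2_PAO") / (k("K_O2_PAO") + SO2)
    no3P = _monod(SNO3, k("K_NO3_PAO"))
    alkP = _monod(SALK, k("K_ALK_PAO"))
    sat_PP = _ratio_monod(XPP, XPAO, k("K_PP"))
    sat_PHA = _ratio_monod(XPHA, XPAO, k("K_PHA"))
    # inhibition as stored poly-P approaches its maximum content K_MAX
    head = np.maximum(k("K_MAX") * XPAO - XPP, 0.0)
    sat_head = _ratio_monod(head, XPAO, k("K_IPP"))
    R[:, 9] = k("q_PHA") * _monod(SA, k("K_A_PAO")) * alkP * sat_PP * XPAO
    storage_pp = (
        k("q_PP") * _monod(SPO4, k("K_PS")) * alkP * sat_PHA * sat_head * XPAO
    )
    R[:, 10] = storage_pp * o2P
    R[:, 11] = storage_pp * k("eta_NO3_PAO") * o2P_off * no3P
    grow_pao = (
        k("mu_PAO") * _monod(SNH4, k("K_NH4_PAO")) * _monod(SPO4, k("K_P_PAO")) * alkP * sat_PHA * XPAO
    )
    R[:, 12] = grow_pao * o2P
    R[:, 13] = grow_pao * k("eta_NO3_PAO") * o2P_off * no3P
    R[:, 14] = k("b_PAO") * XPAO * alkP
    R[:, 15] = k("b_PP") * XPP * alkP
    R[:, 16] = k("b_PHA") * XPHA * alkP

    # autotrophs
    R[:, 17] = (
        k("mu_AUT")
        * _monod(SO2, k("K_O2_AUT"))
        * _monod(SNH4, k("K_NH4_AUT"))
        * _monod(SPO4, k("K_P_AUT"))
        * _monod(SALK, k("K_ALK_AUT"))
        * XAUT
    )
    R[:, 18] = k("b_AUT") * XAUT

    # chemical P (off unless enabled)
    if p.include_chemical_p:
        R[:, 19] = p.k_PRE * SPO4 * c("XMeOH")
        R[:, 20] = p.k_RED * c("XMeP") * _monod(SALK, p.K_ALK_PRE)

    if not np.all(np.isfinite(R)):
        raise FloatingPointError("non-finite process rate")
    return R[0] if single else R


def reactor_derivatives(
    state,
    in_state,
    Q_in: float,
    V: float,
    KLa: float = 0.0,
    SO_sat: float = 8.0,
    params: Asm2dParams | None = None,
    temperature: float = 20.0,
    pm: ProcessMatrix | None = None,
) -> np.ndarray:
    """CSTR mass balance: dC/dt = Q/V (C_in - C) + stoich rates + aeration.

    Aeration enters only the dissolved-oxygen component as
    KLa*(SO_sat - SO2).
    """
    if V <= 0:
        raise ValueError("reactor volume must be positive")
    if Q_in < 0 or KLa < 0:
        raise ValueError("flow and KLa must be non-negative")
    p = params or Asm2dParams()
    pm = pm or stoichiometric_matrix(p)
    arr = state.values if isinstance(state, Asm2dState) else np.asarray(state, dtype=float)
    inn = in_state.values if isinstance(in_state, Asm2dState) else np.asarray(in_state, dtype=float)
    r = process_rates(arr, p, temperature)
    dydt = Q_in / V * (inn - arr) + r @ pm.matrix
    dydt[IDX["SO2"]] += KLa * (SO_sat - arr[IDX["SO2"]])
    return dydt


# composite variables ------------------------------------------------------

_COD_POSITIVE = ("SF", "SA", "SI", "XI", "XS", "XH", "XPAO", "XPHA", "XAUT")


def composite_variables(state, params: Asm2dParams | None = None) -> dict[str, float]:
    """Measured-indicator view of a state: COD, TN, TP, NH4N, TSS (g m^-3).

    COD sums the COD-bearing organics; TN/TP add the organically bound
    fractions to the inorganic species (dissolved N2 is not part of a TN
    measurement); TSS uses the ASM2d solids composition factors.
    """
    p = params or Asm2dParams()
    arr = state.values if isinstance(state, Asm2dState) else np.asarray(state, dtype=float)
    comp = p.composition()

    def c(name):
        return arr[..., IDX[name]]

    cod = sum(c(n) for n in _COD_POSITIVE)
    i_n = comp["N"].copy()
    i_n[IDX["SN2"]] = 0.0
    tn = (arr * i_n).sum(axis=-1) if arr.ndim > 1 else float(arr @ i_n)
    tp = (arr * comp["P"]).sum(axis=-1) if arr.ndim > 1 else float(arr @ comp["P"])
    i_tss = comp["TSS"].copy()
    i_tss[IDX["XTSS"]] = 0.0
    tss = (arr * i_tss).sum(axis=-1) if arr.ndim > 1 else float(arr @ i_tss)
    return {
        "COD": float(cod) if arr.ndim == 1 else cod,
        "TN": tn,
        "TP": tp,
        "NH4N": float(c("SNH4")) if arr.ndim == 1 else c("SNH4"),
        "TSS": tss,
    }
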