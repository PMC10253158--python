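"""Antidiabetic drug-class knowledge used across the pipeline.

ATC level-4 classes under A10B (blood-glucose-lowering drugs excluding
insulins), the insulin group A10A, and the component table for the A10BD
fixed-dose combinations (FDCs), flagging which combination products contain
metformin.  Distinct-drug identity throughout the package is the full ATC
level-5 code; an FDC code counts as one drug.
"""

from __future__ import annotations

from .records import atc_prefix, is_antidiabetic

#: Plain (single-agent) metformin.
METFORMIN_ATC = "A10BA02"

#: ATC level-4 class -> reporting name.
ATCL4_CLASS_NAMES = {
    "A10BA": "biguanides",
    "A10BB": "sulfonylureas",
    "A10BD": "fixed-dose combinations",
    "A10BF": "alpha-glucosidase inhibitors",
    "A10BG": "thiazolidinediones",
    "A10BH": "DPP-4 inhibitors",
    "A10BJ": "GLP-1 receptor agonists",
    "A10BK": "SGLT-2 inhibitors",
    "A10BX": "other blood-glucose-lowering drugs",
}

#: A10BD fixed-dose combinations: code -> (component pair, contains metformin).
FDC_COMPONENTS = {
    "A10BD01": ("phenformin and sulfonylureas", False),
    "A10BD02": ("metformin and sulfonylureas", True),
    "A10BD03": ("metformin and rosiglitazone", True),
    "A10BD04": ("glimepiride and rosiglitazone", False),
    "A10BD05": ("metformin and pioglitazone", True),
    "A10BD06": ("glimepiride and pioglitazone", False),
    "A10BD07": ("metformin and sitagliptin", True),
    "A10BD08": ("metformin and vildagliptin", True),
    "A10BD09": ("pioglitazone and alogliptin", False),
    "A10BD10": ("metformin and saxagliptin", True),
    "A10BD11": ("metformin and linagliptin", True),
    "A10BD12": ("pioglitazone and sitagliptin", False),
    "A10BD13": ("metformin and alogliptin", True),
    "A10BD14": ("metformin and repaglinide", True),
    "A10BD15": ("metformin and dapagliflozin", True),
    "A10BD16": ("metformin and canagliflozin", True),
    "A10BD17": ("metformin and acarbose", True),
    "A10BD18": ("metformin and gemigliptin", True),
    "A10BD19": ("linagliptin and empagliflozin", False),
    "A10BD20": ("metformin and empagliflozin", True),
    "A10BD21": ("saxagliptin and dapagliflozin", False),
    "A10BD22": ("metformin and evogliptin", True),
    "A10BD23": ("metformin and ertugliflozin", True),
    "A10BD24": ("sitagliptin and ertugliflozin", False),
    "A10BD25": ("metformin, linagliptin and empagliflozin", True),
    "A10BD26": ("metformin and lobeglitazone", True),
    "A10BD27": ("metformin, sitagliptin and dapagliflozin", True),
}

#: Metformin-containing products: the single agent plus metformin FDCs.
METFORMIN_CONTAINING = frozenset({METFORMIN_ATC}) | frozenset(
    code for code, (_, has_met) in FDC_COMPONENTS.items() if has_met
)


def is_metformin(code: str) -> bool:
    """True for plain single-agent metformin."""
    return code == METFORMIN_ATC


def is_metformin_fdc(code: str) -> bool:
    """True for a fixed-dose combination product containing metformin."""
    return code != METFORMIN_ATC and code in METFORMIN_CONTAINING


def is_insulin(code: str) -> bool:
    """True for insulins and analogues (ATC A10A)."""
    return is_antidiabetic(code) and atc_prefix(code, 3) == "A10A"


def reporting_class(code: str) -> str:
    """Field reporting class of an antidiabetic level-5 code.

    FDCs are reported as 'fixed-dose combination (<components>)'; all
    insulins roll up into one 'insulins alone or in combination' class;
    other codes report their ATC level-4 class name.
    """
    if not is_antidiabetic(code):
        raise ValueError(f"not an antidiabetic code: {code!r}")
    if is_insulin(code):
        return "insulins alone or in combination"
    l4 = atc_prefix(code, 4)
    if l4 == "A10BD":
        components = FDC_COMPONENTS.get(code, ("unspecified components", False))[0]
        return f"fixed-dose combination ({components})"
    return ATCL4_CLASS_NAMES.get(l4, l4)
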