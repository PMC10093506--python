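"""Self-contained example term dictionary and drug list.

The real regulatory dictionary is licensed, so the package ships a small
fixture hierarchy: the renal SOC with its seven in-scope HLTs and the thirteen
screened PTs, plus decoy terms (urinary-tract infections under the renal SOC,
a general-disorders SOC holding the fluid-retention PT, a gastrointestinal
SOC, and a vascular SOC giving thrombotic microangiopathy a second, non-renal
parent). One branch goes through an HLGT to exercise indirect SOC resolution.
"""
from __future__ import annotations

from .meddra import Term, TermDictionary

__all__ = [
    "TKI_DRUGS",
    "SCREEN_PTS",
    "example_dictionary",
    "PT_CODES",
    "HLT_CODES",
]

#: Index drugs screened by the pipeline (codes are the INN strings).
TKI_DRUGS = ("imatinib", "dasatinib", "nilotinib", "bosutinib", "ponatinib")

#: PT codes of the thirteen screened renal events, in screening order.
SCREEN_PTS = (
    "PT_TIN",   # tubulointerstitial nephritis
    "PT_AKI",   # acute kidney injury
    "PT_CKD",   # chronic kidney disease
    "PT_OLI",   # oliguria
    "PT_RF",    # renal failure
    "PT_RI",    # renal impairment
    "PT_FLU",   # fluid retention
    "PT_RD",    # renal disorder
    "PT_NPH",   # nephropathy
    "PT_TOX",   # toxic nephropathy
    "PT_NS",    # nephrotic syndrome
    "PT_RAS",   # renal artery stenosis
    "PT_TMA",   # thrombotic microangiopathy
)

HLT_CODES = {
    "glomerulonephritis": "HLT_GNS",
    "nephritis": "HLT_NEP",
    "nephropathies": "HLT_NTD",
    "renal_disorders": "HLT_RDN",
    "renal_failure": "HLT_RFI",
    "renal_hypertension": "HLT_RHY",
    "renal_vascular": "HLT_RVI",
}

PT_CODES = {
    "tubulointerstitial nephritis": "PT_TIN",
    "acute kidney injury": "PT_AKI",
    "chronic kidney disease": "PT_CKD",
    "oliguria": "PT_OLI",
    "renal failure": "PT_RF",
    "renal impairment": "PT_RI",
    "fluid retention": "PT_FLU",
    "renal disorder": "PT_RD",
    "nephropathy": "PT_NPH",
    "toxic nephropathy": "PT_TOX",
    "nephrotic syndrome": "PT_NS",
    "renal artery stenosis": "PT_RAS",
    "thrombotic microangiopathy": "PT_TMA",
}

_TERMS = [
    # SOCs
    ("SOC_REN", "Renal and urinary disorders", "SOC"),
    ("SOC_GEN", "General disorders and administration site conditions", "SOC"),
    ("SOC_GI", "Gastrointestinal disorders", "SOC"),
    ("SOC_VAS", "Vascular disorders", "SOC"),
    # optional HLGT exercising indirect HLT->SOC resolution
    ("HLGT_NEP", "Nephropathies", "HLGT"),
    # in-scope renal HLTs
    ("HLT_GNS", "Glomerulonephritis and nephrotic syndrome", "HLT"),
    ("HLT_NEP", "Nephritis NEC", "HLT"),
    ("HLT_NTD", "Nephropathies and tubular disorders NEC", "HLT"),
    ("HLT_RDN", "Renal disorders NEC", "HLT"),
    ("HLT_RFI", "Renal failure and impairment", "HLT"),
    ("HLT_RHY", "Renal hypertension and related conditions", "HLT"),
    ("HLT_RVI", "Renal vascular and ischemic conditions", "HLT"),
    # decoy HLTs
    ("HLT_UTI", "Urinary tract infections", "HLT"),
    ("HLT_FLU", "Oedema and fluid overload NEC", "HLT"),
    ("HLT_NAU", "Nausea and vomiting symptoms", "HLT"),
    ("HLT_EMB", "Embolism and thrombosis", "HLT"),
    # screened PTs
    ("PT_TIN", "Tubulointerstitial nephritis", "PT"),
    ("PT_AKI", "Acute kidney injury", "PT"),
    ("PT_CKD", "Chronic kidney disease", "PT"),
    ("PT_OLI", "Oliguria", "PT"),
    ("PT_RF", "Renal failure", "PT"),
    ("PT_RI", "Renal impairment", "PT"),
    ("PT_FLU", "Fluid retention", "PT"),
    ("PT_RD", "Renal disorder", "PT"),
    ("PT_NPH", "Nephropathy", "PT"),
    ("PT_TOX", "Toxic nephropathy", "PT"),
    ("PT_NS", "Nephrotic syndrome", "PT"),
    ("PT_RAS", "Renal artery stenosis", "PT"),
    ("PT_TMA", "Thrombotic microangiopathy", "PT"),
    # extra in-scope PT under the hypertension HLT
    ("PT_RHT", "Renal hypertension", "PT"),
    # decoy PTs
    ("PT_UTI", "Urinary tract infection", "PT"),
    ("PT_NAUS", "Nausea", "PT"),
    ("PT_VOM", "Vomiting", "PT"),
]

_LINKS = [
    # HLT -> SOC (HLT_NTD goes through the HLGT)
    ("HLT_GNS", "SOC_REN"),
    ("HLT_NEP", "SOC_REN"),
    ("HLGT_NEP", "SOC_REN"),
    ("HLT_NTD", "HLGT_NEP"),
    ("HLT_RDN", "SOC_REN"),
    ("HLT_RFI", "SOC_REN"),
    ("HLT_RHY", "SOC_REN"),
    ("HLT_RVI", "SOC_REN"),
    ("HLT_UTI", "SOC_REN"),
    ("HLT_FLU", "SOC_GEN"),
    ("HLT_NAU", "SOC_GI"),
    ("HLT_EMB", "SOC_VAS"),
    # PT -> HLT
    ("PT_TIN", "HLT_NEP"),
    ("PT_AKI", "HLT_RFI"),
    ("PT_CKD", "HLT_RFI"),
    ("PT_OLI", "HLT_RFI"),
    ("PT_RF", "HLT_RFI"),
    ("PT_RI", "HLT_RFI"),
    ("PT_FLU", "HLT_FLU"),  # outside the seven renal HLTs by design
    ("PT_RD", "HLT_RDN"),
    ("PT_NPH", "HLT_NTD"),
    ("PT_TOX", "HLT_NTD"),
    ("PT_NS", "HLT_GNS"),
    ("PT_RAS", "HLT_RVI"),
    ("PT_TMA", "HLT_RVI"),
    ("PT_TMA", "HLT_EMB"),  # multi-axial: second parent outside the renal SOC
    ("PT_RHT", "HLT_RHY"),
    ("PT_UTI", "HLT_UTI"),
    ("PT_NAUS", "HLT_NAU"),
    ("PT_VOM", "HLT_NAU"),
]


def example_dictionary() -> TermDictionary:
    """The bundled fixture hierarchy (validated on construction)."""
    return TermDictionary([Term(*t) for t in _TERMS], _LINKS)
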