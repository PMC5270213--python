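"""Worked-example data: the bacillibactin-cluster neighborhoods from *B. subtilis*.

The bacillibactin biosynthetic gene cluster (BGC0000309) encodes the
isochorismate synthase DhbC (bsu:BSU31990, EC 5.4.4.2). Its two chromosomal
homologs anchor the classic recruitment story: pabB (bsu:BSU00740,
EC 2.6.1.85, E-value 5e-26), a subunit of para-aminobenzoate synthase in
folate biosynthesis, whose +/-10 neighborhood is dominated by
primary-metabolism genes (13 P, 2 S); and trpE (bsu:BSU22680, EC 4.1.3.27,
E-value 3e-20) inside the trp operon, whose neighborhood carries 17 P and
16 S flags — the S flags there reflect an over-broad secondary-metabolism
pathway assignment rather than true SM membership.

The gene tables below are transcriptions of published annotation tables. The
reference function sets and per-gene pathway assignments are SYNTHETIC
reconstructions: they were derived from the printed P/S flags and the printed
``n_outer/n_inner pathway`` summary rows (only assignments those rows fix
unambiguously are planted), so the loaders reproduce the published tallies
without access to the underlying databases.
"""

from __future__ import annotations

from .neighborhood import GeneRecord
from .ec import parse_ec

__all__ = [
    "bacillibactin_pm_function_keys",
    "bacillibactin_sm_function_keys",
    "pabb_genome",
    "trpe_genome",
    "pabb_anchor",
    "trpe_anchor",
    "bacillibactin_pairs",
    "PATHWAY_NAMES",
]

pabb_anchor = "bsu:BSU00740"
trpe_anchor = "bsu:BSU22680"

#: (bgc_id, sm_annotation, homolog gene id, E-value) for the two homolog pairs.
bacillibactin_pairs = (
    ("BGC0000309", "bsu:BSU31990 Isochorismate synthase DhbC (EC 5.4.4.2)", pabb_anchor, 5e-26),
    ("BGC0000309", "bsu:BSU31990 Isochorismate synthase DhbC (EC 5.4.4.2)", trpe_anchor, 3e-20),
)

PATHWAY_NAMES = {
    "bsu00130": "Ubiquinone and other terpenoid-quinone biosynthesis",
    "bsu00230": "Purine metabolism",
    "bsu00270": "Cysteine and methionine metabolism",
    "bsu00400": "Phenylalanine, tyrosine and tryptophan biosynthesis",
    "bsu00770": "Pantothenate and CoA biosynthesis",
    "bsu00790": "Folate biosynthesis",
    "bsu00900": "Terpenoid backbone biosynthesis",
    "bsu00920": "Sulfur metabolism",
    "bsu00970": "Aminoacyl-tRNA biosynthesis",
    "bsu01110": "Biosynthesis of secondary metabolites",
    "bsu01130": "Biosynthesis of antibiotics",
    "bsu01230": "Biosynthesis of amino acids",
    "bsu02030": "Bacterial chemotaxis",
}

# (ordinal, gene_id, product, ec, pathways) — ec and pathways ";"-separated.
_PABB_ROWS = (
    (64, "bsu:BSU00640", "spoIIE; stage II sporulation protein E", "3.1.3.16", ""),
    (65, "bsu:BSU00650", "yabS; hypothetical protein", "", ""),
    (66, "bsu:BSU00660", "yabT; serine/threonine protein kinase", "2.7.11.1", ""),
    (67, "bsu:BSU00670", "tilS; tRNA(Ile)-lysidine synthase", "6.3.4.19", ""),
    (68, "bsu:BSU00680", "hprT; hypoxanthine-guanine phosphoribosyltransferase", "2.4.2.8", "bsu01110;bsu00230"),
    (69, "bsu:BSU00690", "ftsH; ATP-dependent zinc metalloprotease FtsH", "3.4.24.-", ""),
    (70, "bsu:BSU00700", "coaX; type III pantothenate kinase", "2.7.1.33", "bsu00770"),
    (71, "bsu:BSU00710", "hslO; 33 kDa chaperonin", "", ""),
    (72, "bsu:BSU00720", "yacD; peptidyl-prolyl cis-trans isomerase", "", ""),
    (73, "bsu:BSU00730", "cysK; cysteine synthase", "2.5.1.47", "bsu01110;bsu00270;bsu00920;bsu01130;bsu01230"),
    (74, "bsu:BSU00740", "pabB; para-aminobenzoate synthase component I", "2.6.1.85", "bsu00790"),
    (75, "bsu:BSU00750", "pabA; para-aminobenzoate/anthranilate synthase component II", "2.6.1.85", "bsu00790"),
    (76, "bsu:BSU00760", "pabC; aminodeoxychorismate lyase", "4.1.3.38", "bsu00790"),
    (77, "bsu:BSU00770", "sul; dihydropteroate synthase", "2.5.1.15", "bsu00790"),
    (78, "bsu:BSU00780", "folB; dihydroneopterin aldolase", "4.1.2.25", "bsu00790"),
    (79, "bsu:BSU00790", "folK; 2-amino-4-hydroxy-6-hydroxymethyldihydropteridine pyrophosphokinase", "2.7.6.3", "bsu00790"),
    (80, "bsu:BSU00800", "yazB; XRE family transcriptional regulator", "", ""),
    (81, "bsu:BSU00810", "dusB; tRNA-dihydrouridine synthase", "1.-.-.-", ""),
    (82, "bsu:BSU00820", "lysS; lysine--tRNA ligase", "6.1.1.6", "bsu00970"),
    (83, "bsu:BSU00830", "ctsR; transcriptional regulator CtsR", "", ""),
    (84, "bsu:BSU00840", "mcsA; protein arginine kinase activator", "", ""),
)

_TRPE_ROWS = (
    # offset -10 gene reconstructed as an unlabeled placeholder (no EC, no pathways)
    (258, "bsu:BSU22580", "hypothetical protein", "", ""),
    (259, "bsu:BSU22590", "ypiA; TPR repeat-containing protein YpiA", "", ""),
    (260, "bsu:BSU22600", "aroE; 3-phosphoshikimate 1-carboxyvinyltransferase", "2.5.1.19", "bsu01110;bsu00400"),
    (261, "bsu:BSU22610", "tyrA; prephenate dehydrogenase", "1.3.1.12", "bsu01110;bsu00400"),
    (262, "bsu:BSU22620", "hisC; histidinol-phosphate aminotransferase", "2.6.1.9", "bsu01110;bsu00400"),
    (263, "bsu:BSU22630", "trpA; tryptophan synthase alpha chain", "4.2.1.20", "bsu01110;bsu00400"),
    (264, "bsu:BSU22640", "trpB; tryptophan synthase beta chain", "4.2.1.20", "bsu01110;bsu00400"),
    (265, "bsu:BSU22650", "trpF; N-(5'-phosphoribosyl)anthranilate isomerase", "5.3.1.24", "bsu01110;bsu00400"),
    (266, "bsu:BSU22660", "trpC; indole-3-glycerol phosphate synthase", "4.1.1.48", "bsu01110;bsu00400"),
    (267, "bsu:BSU22670", "trpD; anthranilate phosphoribosyltransferase", "2.4.2.18", "bsu01110;bsu00400"),
    (268, "bsu:BSU22680", "trpE; anthranilate synthase component 1", "4.1.3.27", "bsu01110;bsu00400"),
    (269, "bsu:BSU22690", "aroH; chorismate mutase AroH", "5.4.99.5", "bsu01110;bsu00400"),
    (270, "bsu:BSU22700", "aroB; 3-dehydroquinate synthase", "4.2.3.4", "bsu01110;bsu00400"),
    (271, "bsu:BSU22710", "aroF; chorismate synthase", "4.2.3.5", "bsu01110;bsu00400"),
    (272, "bsu:BSU22720", "cheR; chemotaxis protein methyltransferase", "2.1.1.80", "bsu02030"),
    (273, "bsu:BSU22730", "ndk; nucleoside diphosphate kinase", "2.7.4.6", "bsu01110;bsu00230"),
    (274, "bsu:BSU22740", "hepT; heptaprenyl diphosphate synthase component 2", "2.5.1.30", "bsu01110;bsu00900"),
    (275, "bsu:BSU22750", "ubiE; demethylmenaquinone methyltransferase", "2.1.1.-", "bsu01110;bsu00130"),
    (276, "bsu:BSU22760", "hepS; heptaprenyl diphosphate synthase component 1", "2.5.1.30", "bsu01110;bsu00900"),
    (277, "bsu:BSU22770", "mtrB; transcription attenuation protein MtrB", "", ""),
    (278, "bsu:BSU22780", "folE; GTP cyclohydrolase 1", "3.5.4.16", "bsu00790"),
)


def _build(rows) -> list[GeneRecord]:
    genes = []
    for ordinal, gene_id, product, ec, pathways in rows:
        ec_list = tuple(parse_ec(p) for p in ec.split(";") if p)
        pw = frozenset(p for p in pathways.split(";") if p)
        genes.append(
            GeneRecord(
                replicon_id="bsu_chr",
                ordinal=ordinal,
                gene_id=gene_id,
                strand="+",
                product=product,
                ec_list=ec_list,
                pathway_ids=pw,
            )
        )
    return genes


def pabb_genome() -> list[GeneRecord]:
    """The +/-10 gene span around pabB (21 genes, ordinals 64..84)."""
    return _build(_PABB_ROWS)


def trpe_genome() -> list[GeneRecord]:
    """The +/-10 gene span around trpE (21 genes, ordinals 258..278)."""
    return _build(_TRPE_ROWS)


def bacillibactin_pm_function_keys() -> frozenset[str]:
    """Full-EC keys occurring in the primary-metabolism reference set.

    Synthetic reconstruction from the printed P flags (see module docstring).
    """
    return frozenset(
        {
            "3.1.3.16", "2.7.11.1", "6.3.4.19", "2.4.2.8", "2.7.1.33", "2.5.1.47",
            "2.6.1.85", "4.1.3.38", "2.5.1.15", "4.1.2.25", "2.7.6.3", "6.1.1.6",
            "2.5.1.19", "1.3.1.12", "2.6.1.9", "4.2.1.20", "5.3.1.24", "4.1.1.48",
            "2.4.2.18", "4.1.3.27", "5.4.99.5", "4.2.3.4", "4.2.3.5", "2.1.1.80",
            "2.7.4.6", "2.5.1.30", "3.5.4.16",
        }
    )


def bacillibactin_sm_function_keys() -> frozenset[str]:
    """EC strings mapped to the secondary-metabolite biosynthesis pathway.

    Synthetic reconstruction from the printed S flags; includes the wildcarded
    entry ``2.1.1.-`` carried by ubiE.
    """
    return frozenset(
        {
            "2.4.2.8", "2.5.1.47",
            "2.5.1.19", "1.3.1.12", "2.6.1.9", "4.2.1.20", "5.3.1.24", "4.1.1.48",
            "2.4.2.18", "4.1.3.27", "5.4.99.5", "4.2.3.4", "4.2.3.5", "2.7.4.6",
            "2.5.1.30", "2.1.1.-",
        }
    )
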