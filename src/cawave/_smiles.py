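"""Small bundled SMILES pool for assigning structures to simulated compounds.

Structures are assigned to synthetic compounds at random, independently of the
simulated waveform effect, so fingerprints carry no activity signal by
construction.
"""

SMILES_POOL = [
    "CC(=O)Oc1ccccc1C(=O)O",            # aspirin
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",       # caffeine
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",       # ibuprofen
    "CC(=O)Nc1ccc(O)cc1",               # paracetamol
    "Clc1ccccc1",                        # chlorobenzene
    "c1ccc2c(c1)cccn2",                  # quinoline
    "OCC(O)CO",                          # glycerol
    "CCO",                               # ethanol
    "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1",    # salbutamol
    "CN1CCC[C@H]1c1cccnc1",             # nicotine
    "OC(=O)c1ccccc1O",                  # salicylic acid
    "Nc1ccc(cc1)S(N)(=O)=O",            # sulfanilamide
    "CC(N)Cc1ccccc1",                   # amphetamine
    "COc1ccc2cc(ccc2c1)C(C)C(=O)O",     # naproxen
    "NC(=O)c1ccccc1",                   # benzamide
    "Oc1ccccc1",                         # phenol
    "CC(=O)NCCc1c[nH]c2ccc(OC)cc12",    # melatonin
    "OC(=O)CC(O)(CC(=O)O)C(=O)O",       # citric acid
    "NCCc1ccc(O)c(O)c1",                # dopamine
    "C1CCNCC1",                          # piperidine
    "c1ccsc1",                           # thiophene
    "OCCN1CCN(CCCN2c3ccccc3Sc3ccc(Cl)cc23)CC1",  # perphenazine-like
    "CN(C)CCOC(c1ccccc1)c1ccccc1",      # diphenhydramine
    "CCN(CC)CC(=O)Nc1c(C)cccc1C",       # lidocaine
    "Cc1ccccc1N",                        # o-toluidine
    "OC(=O)c1cccnc1",                   # nicotinic acid
    "Clc1ccc(cc1)C(c1ccccc1)N1CCN(CCOCCO)CC1",  # hydroxyzine-like
    "COc1cc2c(cc1OC)CCN(C)C2",          # tetrahydroisoquinoline deriv.
    "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1",   # atenolol
    "CC(C)NCC(O)COc1cccc2ccccc12",      # propranolol
    "OCC1OC(O)C(O)C(O)C1O",             # glucose
    "NC(Cc1ccccc1)C(=O)O",              # phenylalanine
    "NC(CO)C(=O)O",                     # serine
    "CSCCC(N)C(=O)O",                   # methionine
    "OC(=O)c1ccc(cc1)C(=O)O",           # terephthalic acid
    "Nc1ncnc2[nH]cnc12",                # adenine
    "O=c1cc[nH]c(=O)[nH]1",             # uracil
    "Cc1c[nH]c(=O)[nH]c1=O",            # thymine
    "c1ccc(cc1)c1ccccc1",               # biphenyl
    "OCc1ccccc1",                        # benzyl alcohol
    "CC(=O)c1ccccc1",                   # acetophenone
    "CCOC(=O)c1ccccc1",                 # ethyl benzoate
    "CN1CCN(CC1)c1ccccc1",              # phenylpiperazine
    "OC(c1ccccc1)c1ccccc1",             # benzhydrol
    "O=C(Nc1ccccc1)c1ccccc1",           # benzanilide
    "CC1(C)SC2C(NC(=O)Cc3ccccc3)C(=O)N2C1C(=O)O",  # penicillin G
    "CN1C(=O)CN=C(c2ccccc2)c2cc(Cl)ccc12",          # diazepam
    "CCCCc1oc2ccccc2c1C(=O)c1cc(I)c(OCCN(CC)CC)c(I)c1",  # amiodarone
]
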