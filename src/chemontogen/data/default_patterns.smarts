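# Default predefined pattern library (curated, versioned; swappable via
# --pattern-library).  One SMARTS per line; '#' starts a comment.
#
# Common functional groups
[OX2H]                      # hydroxyl
[#6][OX2H]                  # carbinol / alcohol carbon
[OX2H][CX4]                 # aliphatic alcohol
[CX3]=[OX1]                 # carbonyl
[CX3H1]=O                   # aldehyde
[CX3](=O)[#6]               # ketone-like carbonyl
C(=O)[OX2H]                 # carboxylic acid
C(=O)[OX1-]                 # carboxylate
C(=O)O[#6]                  # carboxylic acid ester (O-linked)
C(=[O,S])OC                 # general ester (thio tolerant)
C(=O)N                      # amide
C(=O)Cl                     # acid chloride
[NX3;H2][CX4]               # primary aliphatic amine
[NX3;H1]([CX4])[CX4]        # secondary aliphatic amine
[NX3]([CX4])([CX4])[CX4]    # tertiary aliphatic amine
[NX3][CX3]=[OX1]            # amide nitrogen
[NX2]=[CX3]                 # imine
C#N                         # nitrile
[N+](=O)[O-]                # nitro
N=[N+]=[N-]                 # azide
NN                          # hydrazine
[NX3][OX2H]                 # hydroxylamine
[OX2]([#6])[#6]             # ether oxygen
[SX2H]                      # thiol
[SX2]([#6])[#6]             # thioether
S(=O)(=O)[OX2H]             # sulfonic acid
S(=O)(=O)N                  # sulfonamide
P(=O)(O)(O)O                # phosphate
[OX2][OX2]                  # peroxide
[F,Cl,Br,I]                 # any halogen
[CX4][F,Cl,Br,I]            # alkyl halide
c[OX2H]                     # phenol
c[NX3;H2]                   # aniline-like amine
C=C                         # alkene
C#C                         # alkyne
cc                          # aromatic pair
[$([cX3](:*):*)]            # aromatic carbon (recursive form)
#
# Ring-count primitives
[R1]                        # atom in exactly one ring
[R2]                        # atom in two rings (fused systems)
[r3]                        # three-membered ring atom
[r4]
[r5]
[r6]
#
# Heteroaromatics and misc scaffolds
o1cccc1                     # furan
n1ccccc1                    # pyridine
s1cccc1                     # thiophene
c1ccccc1                    # benzene ring
C1CCCCC1                    # cyclohexane ring
[nX3H1]                     # pyrrole-type NH
[#7;R]                      # ring nitrogen
[#8;R]                      # ring oxygen
[#16;R]                     # ring sulfur
#
# Carbonyl neighborhood patterns
O=C[OX2H0]                  # ester-like carbonyl-oxygen
O=CN                        # amide backbone
O=C(N)N                     # urea
N=C(N)N                     # guanidine
O=C(O)O                     # carbonate-like
[CX3](=O)[OX2][CX3](=O)     # anhydride
#
# Hydrogenation-state primitives
[CX4H3]                     # methyl carbon
[CX4H2]                     # methylene carbon
[CX4H1]                     # methine carbon
[NX3H2]                     # primary amine nitrogen
[OX2H2]                     # water-like oxygen
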