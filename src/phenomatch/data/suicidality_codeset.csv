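pattern,subtype
# Reference suicidality codeset (synthetic stand-in for the full published
# 1396-code list, which is distributed externally).  Exact codes below are
# the individually documented ideation / attempt / history codes; the
# intentional-self-harm families are expressed as prefixes (X71-X83).
# Substitute your own file via the codeset_path config key to use an
# exact enumerated list.
R45851,ideation
T1491,attempt
T1491XA,attempt
T1491XD,attempt
T1491XS,attempt
R4588,history_of_self_harm
Z915,history_of_self_harm
Z9151,history_of_self_harm
Z9152,history_of_self_harm
X71*,self_harm
X72*,self_harm
X73*,self_harm
X74*,self_harm
X75*,self_harm
X76*,self_harm
X77*,self_harm
X78*,self_harm
X79*,self_harm
X80*,self_harm
X81*,self_harm
X82*,self_harm
X83*,self_harm
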