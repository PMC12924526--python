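synonym,label
y,Yes
yes.,Yes
positive,Yes
n,No
negative,No
none,No
absent,No
not specified,Unspecified
not mentioned,Unspecified
unknown,Unspecified
n/a,Unspecified
na,Unspecified
nd,Newly diagnosed
newly dx,Newly diagnosed
new diagnosis,Newly diagnosed
relapse,Relapsed
recurrent,Relapsed
in remission,Remission
present,Present
scr,Stringent Complete Response
cr,Complete Response
vgpr,Very Good Partial Response
pr,Partial Response
mr,Minimal Response
sd,No Response
stable disease,No Response
pd,Progressive Disease
progression,Progressive Disease
transplant eligible,Eligible
transplant ineligible,Ineligible
deferred,Eligible but deferred
transplant performed,Performed
paramedullary disease,Paramedullary
soft-tissue,Soft tissue
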