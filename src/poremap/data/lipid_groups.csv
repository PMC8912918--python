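resname,head_group,tail_group,charge
APC,LPC,PU,0.0
BNSM,SM,MU,0.0
CHOL,CHOL,,0.0
DAPC,PC,PU,0.0
DAPE,PE,PU,0.0
DAPS,PS,PU,-1.0
DBCE,CE,FS,0.0
DBG1,GM,FS,0.0
DBG3,GM,FS,0.0
DBGS,GM,FS,0.0
DBSM,SM,FS,0.0
DOPC,PC,MU,0.0
DOPE,PE,MU,0.0
DOPS,PS,MU,-1.0
DPCE,CE,FS,0.0
DPG1,GM,FS,0.0
DPG3,GM,FS,0.0
DPGS,GM,FS,0.0
DPPC,PC,FS,0.0
DPPS,PS,FS,-1.0
DPSM,SM,FS,0.0
DUPE,PE,PU,0.0
DUPS,PS,PU,-1.0
DXCE,CE,FS,0.0
DXG1,GM,FS,0.0
DXG3,GM,FS,0.0
DXSM,SM,FS,0.0
IPC,LPC,PU,0.0
IPE,LPC,PU,0.0
OAPE,PE,PU,0.0
OIPC,PC,PU,0.0
OIPE,PE,PU,0.0
OPC,LPC,MU,0.0
OUPC,PC,PU,0.0
OUPE,PE,PU,0.0
OUPS,PS,PU,-1.0
PADG,DAG,PU,0.0
PAP1,PIP,PU,-3.0
PAP2,PIP,PU,-5.0
PAP3,PIP,PU,-7.0
PAPA,PA,PU,-1.0
PAPC,PC,PU,0.0
PAPE,PE,PU,0.0
PAPI,PI,PU,-1.0
PAPS,PS,PU,-1.0
PBSM,SM,FS,0.0
PEPC,PC,PU,0.0
PFPC,PC,PU,0.0
PGSM,SM,MU,0.0
PIDG,DAG,PU,0.0
PIPA,PA,PU,-1.0
PIPC,PC,PU,0.0
PIPE,PE,PU,0.0
PIPI,PI,PU,-1.0
PIPS,PS,PU,-1.0
PNCE,CE,MU,0.0
PNG1,GM,MU,0.0
PNG3,GM,MU,0.0
PNGS,GM,MU,0.0
PNSM,SM,MU,0.0
POCE,CE,MU,0.0
PODG,DAG,MU,0.0
POG1,GM,MU,0.0
POG3,GM,MU,0.0
POGS,GM,MU,0.0
POP1,PIP,MU,-3.0
POP2,PIP,MU,-5.0
POP3,PIP,MU,-7.0
POPA,PA,MU,-1.0
POPC,PC,MU,0.0
POPE,PE,MU,0.0
POPI,PI,MU,-1.0
POPS,PS,MU,-1.0
POSM,SM,MU,0.0
PPC,LPC,FS,0.0
PPE,LPC,FS,0.0
PQPE,PE,PU,0.0
PQPS,PS,PU,-1.0
PUDG,DAG,PU,0.0
PUPA,PA,PU,-1.0
PUPC,PC,PU,0.0
PUPE,PE,PU,0.0
PUPI,PI,PU,-1.0
PUPS,PS,PU,-1.0
UPC,LPC,PU,0.0
XNCE,CE,MU,0.0
XNG1,GM,MU,0.0
XNG3,GM,MU,0.0
XNSM,SM,MU,0.0
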