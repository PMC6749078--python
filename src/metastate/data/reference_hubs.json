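{
  "state1": ["PreCG.L", "PreCG.R", "ROL.L", "ROL.R", "SMA.L", "SMA.R", "INS.L", "INS.R", "PoCG.L", "PoCG.R", "SMG.L", "SMG.R", "PCL.L", "HES.L", "HES.R", "STG.L", "STG.R"],
  "state2": ["CAL.L", "CAL.R", "CUN.L", "CUN.R", "LING.L", "LING.R", "SOG.L", "SOG.R", "MOG.L", "MOG.R", "IOG.L", "IOG.R", "FFG.L", "FFG.R", "PoCG.L", "PoCG.R"],
  "state3": ["PCG.L", "SFGmed.L", "SFGmed.R", "ORBsupmed.L", "ORBsupmed.R", "REC.L", "REC.R", "ACG.L", "MTG.L", "MTG.R", "OLF.L", "OLF.R", "TPOmid.L", "TPOmid.R", "ANG.L", "ANG.R"],
  "state4": ["ROL.L", "ROL.R", "SMA.R", "INS.L", "INS.R", "HES.L", "HES.R", "ACG.L", "ACG.R", "DCG.L", "DCG.R", "CAU.L", "PUT.L", "PUT.R", "PAL.L", "PAL.R", "THA.L", "THA.R"],
  "state5": ["SMG.L", "SMG.R", "ORBsup.R", "IPL.L", "IPL.R", "MFG.L", "MFG.R", "ORBmid.L", "ORBmid.R", "IFGoperc.L", "IFGoperc.R", "IFGtriang.L", "IFGtriang.R", "ORBinf.L", "ORBinf.R"],
  "structural": ["SFGdor.L", "SFGdor.R", "SMA.L", "SMA.R", "SFGmed.L", "DCG.R", "SOG.L", "SOG.R", "MOG.L", "PCUN.L", "PCUN.R", "PUT.L", "PUT.R", "THA.L", "THA.R"],
  "subnetwork_assignment": {"state1": "SMN", "state2": "OCC", "state3": "DMN", "state4": "CON", "state5": "FPN"}
}
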