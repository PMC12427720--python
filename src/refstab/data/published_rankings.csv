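panel,method,ordering
all,delta_ct,60SrRNA;SKD1;ACT;eIF6A;NDUFA13;GAPDH;EF-1γ;TUA;UBC;UBQ;TUB;YLS8
all,bestkeeper,SKD1;EF-1γ;60SrRNA;ACT;GAPDH;eIF6A;UBQ;UBC;NDUFA13;YLS8;TUA;TUB
all,normfinder,eIF6A;60SrRNA;SKD1;NDUFA13;ACT;GAPDH;EF-1γ;TUA;UBC;UBQ;TUB;YLS8
all,genorm,ACT|SKD1;60SrRNA;GAPDH;NDUFA13;EF-1γ;eIF6A;TUA;UBC;UBQ;TUB;YLS8
all,comprehensive,SKD1;60SrRNA;ACT;eIF6A;EF-1γ;GAPDH;NDUFA13;TUA;UBC;UBQ;TUB;YLS8
leaves,delta_ct,60SrRNA;YLS8;GAPDH;ACT;eIF6A;UBC;TUA;SKD1;EF-1γ;NDUFA13;UBQ;TUB
leaves,bestkeeper,EF-1γ;SKD1;ACT;60SrRNA;YLS8;UBC;TUA;GAPDH;eIF6A;UBQ;NDUFA13;TUB
leaves,normfinder,GAPDH;YLS8;60SrRNA;eIF6A;ACT;UBC;TUA;SKD1;NDUFA13;UBQ;EF-1γ;TUB
leaves,genorm,EF-1γ|SKD1;ACT;60SrRNA;YLS8;UBC;GAPDH;TUA;eIF6A;NDUFA13;UBQ;TUB
leaves,comprehensive,60SrRNA;EF-1γ;YLS8;SKD1;GAPDH;ACT;UBC;eIF6A;TUA;NDUFA13;UBQ;TUB
rhizomes,delta_ct,60SrRNA;SKD1;NDUFA13;ACT;eIF6A;GAPDH;EF-1γ;TUA;UBC;UBQ;TUB;YLS8
rhizomes,bestkeeper,60SrRNA;SKD1;ACT;eIF6A;NDUFA13;EF-1γ;GAPDH;TUA;UBQ;UBC;YLS8;TUB
rhizomes,normfinder,eIF6A;60SrRNA;SKD1;NDUFA13;ACT;EF-1γ;GAPDH;TUA;UBQ;UBC;YLS8;TUB
rhizomes,genorm,ACT|NDUFA13;SKD1;60SrRNA;GAPDH;EF-1γ;eIF6A;TUA;UBC;UBQ;TUB;YLS8
rhizomes,comprehensive,60SrRNA;SKD1;NDUFA13;ACT;eIF6A;GAPDH;EF-1γ;TUA;UBC;UBQ;TUB;YLS8
flowers,delta_ct,SKD1;TUB;GAPDH;YLS8;TUA;EF-1γ;ACT;NDUFA13;eIF6A;UBC;60SrRNA;UBQ
flowers,bestkeeper,EF-1γ;UBQ;TUB;ACT;eIF6A;GAPDH;SKD1;TUA;YLS8;60SrRNA;NDUFA13;UBC
flowers,normfinder,SKD1;TUB;GAPDH;EF-1γ;ACT;TUA;YLS8;eIF6A;NDUFA13;UBC;60SrRNA;UBQ
flowers,genorm,GAPDH|TUA;TUB;ACT;SKD1;YLS8;NDUFA13;UBC;EF-1γ;eIF6A;60SrRNA;UBQ
flowers,comprehensive,SKD1;TUB;GAPDH;EF-1γ;TUA;ACT;YLS8;UBQ;eIF6A;NDUFA13;UBC;60SrRNA
R. japonica,delta_ct,60SrRNA;UBC;ACT;EF-1γ;SKD1;NDUFA13;GAPDH;TUA;UBQ;TUB;eIF6A;YLS8
R. japonica,bestkeeper,UBQ;GAPDH;UBC;TUA;60SrRNA;EF-1γ;SKD1;ACT;NDUFA13;TUB;eIF6A;YLS8
R. japonica,normfinder,SKD1;EF-1γ;60SrRNA;UBC;ACT;GAPDH;TUA;UBQ;NDUFA13;TUB;eIF6A;YLS8
R. japonica,genorm,EF-1γ|SKD1;UBC;60SrRNA;ACT;NDUFA13;GAPDH;TUA;UBQ;TUB;eIF6A;YLS8
R. japonica,comprehensive,SKD1;EF-1γ;60SrRNA;UBC;GAPDH;ACT;UBQ;TUA;NDUFA13;TUB;eIF6A;YLS8
R. x bohemica,delta_ct,UBC;eIF6A;60SrRNA;ACT;GAPDH;YLS8;TUB;UBQ;NDUFA13;SKD1;EF-1γ;TUA
R. x bohemica,bestkeeper,EF-1γ;SKD1;60SrRNA;ACT;YLS8;UBC;eIF6A;GAPDH;TUB;UBQ;NDUFA13;TUA
R. x bohemica,normfinder,UBC;60SrRNA;eIF6A;ACT;GAPDH;YLS8;TUB;UBQ;NDUFA13;SKD1;TUA;EF-1γ
R. x bohemica,genorm,eIF6A|UBQ;UBC;TUB;NDUFA13;GAPDH;60SrRNA;ACT;YLS8;SKD1;EF-1γ;TUA
R. x bohemica,comprehensive,UBC;eIF6A;60SrRNA;ACT;UBQ;GAPDH;EF-1γ;YLS8;TUB;SKD1;NDUFA13;TUA
R. sachalinensis,delta_ct,eIF6A;60SrRNA;SKD1;ACT;NDUFA13;GAPDH;EF-1γ;YLS8;UBC;TUA;UBQ;TUB
R. sachalinensis,bestkeeper,eIF6A;60SrRNA;SKD1;NDUFA13;ACT;GAPDH;EF-1γ;YLS8;UBC;TUA;UBQ;TUB
R. sachalinensis,normfinder,eIF6A;60SrRNA;NDUFA13;SKD1;ACT;GAPDH;YLS8;EF-1γ;UBC;TUA;UBQ;TUB
R. sachalinensis,genorm,ACT|SKD1;EF-1γ;GAPDH;60SrRNA;NDUFA13;eIF6A;YLS8;UBC;TUA;UBQ;TUB
R. sachalinensis,comprehensive,eIF6A;SKD1;60SrRNA;ACT;NDUFA13;GAPDH;EF-1γ;YLS8;UBC;TUA;UBQ;TUB
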