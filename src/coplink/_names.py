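"""Name pools, nickname table and a synthetic postcode gazetteer.

The forename pool is curated so that distinct base forenames are not
Jaro-Winkler-similar to each other (checked in the test suite): name
similarity in synthetic data then arises only through the deliberate
corruption processes (nickname substitution, typos), never by accident
of the pool itself.  Surnames are synthetic root+suffix composites and
postcodes come from an invented gazetteer; neither resembles real data.
"""

from __future__ import annotations

# (formal forename, sex) pool.  Early-1990s British-flavoured, length >= 4.
MALE_FORENAMES = [
    "JAMES", "DANIEL", "THOMAS", "MATTHEW", "CHRISTOPHER", "JOSHUA",
    "MICHAEL", "RYAN", "LUKE", "SAMUEL", "JORDAN", "ADAM", "CALLUM",
    "BENJAMIN", "ALEXANDER", "CONNOR", "LIAM", "JACOB", "KIERAN",
    "NATHAN", "GORDON", "OLIVER", "WILLIAM", "HARRY", "DOUGLAS",
    "ROBERT", "EDWARD", "JOSEPH", "LEWIS", "AARON", "BRADLEY",
    "SCOTT", "CRAIG", "STUART", "GARETH", "DUNCAN", "FERGUS",
    "RUSSELL", "TREVOR", "VINCENT",
]
FEMALE_FORENAMES = [
    "REBECCA", "LAUREN", "JESSICA", "CHARLOTTE", "HANNAH", "SOPHIE",
    "CATHERINE", "ELIZABETH", "VICTORIA", "NATASHA", "GEMMA", "HOLLY",
    "BETHANY", "CHELSEA", "SIOBHAN", "STEPHANIE", "NICOLA", "RACHEL",
    "KIRSTY", "LEANNE", "MEGAN", "ABIGAIL", "FRANCESCA", "GEORGINA",
    "IMOGEN", "JASMINE", "KAYLEIGH", "LYDIA", "MIRANDA", "NAOMI",
    "PHILIPPA", "ROSEMARY", "SHANNON", "TABITHA", "URSULA", "VANESSA",
    "WENDY", "YASMIN", "ZOEANN", "PAULINE",
]

# formal form -> plausible short forms / variants seen in police records
NICKNAMES = {
    "JAMES": ["JAMIE", "JIMMY"],
    "DANIEL": ["DANNY"],
    "THOMAS": ["TOMMY"],
    "MATTHEW": ["MATTY"],
    "CHRISTOPHER": ["CHRIS"],
    "MICHAEL": ["MICKY", "MIKE"],
    "SAMUEL": ["SAMMY"],
    "BENJAMIN": ["BENNY"],
    "ALEXANDER": ["ALEX"],
    "NATHAN": ["NAT"],
    "WILLIAM": ["BILLY", "WILL"],
    "ROBERT": ["BOBBY", "ROB"],
    "EDWARD": ["EDDIE", "TEDDY"],
    "JOSEPH": ["JOEY"],
    "REBECCA": ["BECKY"],
    "JESSICA": ["JESS"],
    "CHARLOTTE": ["LOTTIE"],
    "CATHERINE": ["KATHERINE", "KATE", "CATHY"],
    "ELIZABETH": ["LIZZIE", "BETH"],
    "VICTORIA": ["VICKY"],
    "STEPHANIE": ["STEPH"],
    "ABIGAIL": ["ABBIE"],
    "FRANCESCA": ["FRAN"],
    "GEORGINA": ["GEORGIE"],
    "PHILIPPA": ["PIPPA"],
}

# Synthetic surname pool: syllable composites culled so that no two pool
# members are Jaro-Winkler similar (>= 0.85) to each other -- accidental
# surname similarity between distinct people is then as rare as in real
# populations, and any observed similarity traces back to a deliberate
# corruption process.
SURNAMES = [
    "LEACKMERE", "HAREMTON", "DRIDTON", "GUTTLEIGH", "STUGSTOW", "WEADTON",
    "SUGBOURNE", "FEADDALE", "HICKWELL", "WHUGMERE", "CREANDWORTH",
    "FLUSSHURST", "YALLWORTH", "NEXLEIGH", "BREMWOOD", "DENHURST",
    "DRONWOOD", "BRAXWELL", "COGWOOD", "WHEANDALE", "TRUDCOMBE",
    "STACKCOMBE", "HOOSSTON", "DRILLDALE", "DREMBOURNE", "PRARNWOOD",
    "DATTCOMBE", "DROOSSWORTH", "GUNDCOTT", "YOORTON", "DREGWOOD",
    "HARIGBY", "DRESSFORD", "HADWELL", "WETTDALE", "WERNFORD", "PRUXFIELD",
    "GOONDFIELD", "TOODBOURNE", "GEARSTOW", "KIRSHAW", "GREARCOMBE",
    "FLIGWOOD", "TREADWOOD", "CRULLBY", "NEMSTOW", "FIXHURST", "KASSMERE",
    "HAROOCKTON", "GRENTON", "FAGWORTH", "HOOCKFORD", "CROGDALE",
    "DREAMFIELD", "PRUTTTON", "PARNBOURNE", "SUNLEIGH", "MORWOOD",
    "HAREACKBY", "HAREARNWOOD", "HORFIELD", "HINDMERE", "DOSSFIELD",
    "SARWORTH", "BRILLWORTH", "LELLHURST", "SULLCOMBE", "DRERNDALE",
    "COODWORTH", "HAREAXWELL", "TRORNFORD", "TORNWORTH", "PARNSTOW",
    "FLORCOTT", "LODHURST", "FLOMTON", "SAGDALE", "WUNDSHAW", "SEAGWOOD",
    "PEAXSHAW", "BOORHURST", "VEALLMERE", "BEANDSTOW", "FUMFORD",
    "COOLLSHAW", "SUGHURST", "FESSMERE", "PICKDALE", "YEATTWELL", "SUMMERE",
    "LAXWORTH", "TRINDBY", "NANDWORTH", "WOLLWOOD", "HARETTSHAW", "DOGMERE",
    "HEASSHURST", "LANFORD", "VURWOOD", "DUNMERE", "YUGCOMBE", "MEACKWELL",
    "WHILLTON", "NISSFORD", "LIDBOURNE", "DRUCKWORTH", "WHOGSTOW",
    "BANSHAW", "HOCKWORTH", "FLIDLEIGH", "TRITTFIELD", "PEGDALE",
    "VILLSHAW", "HARADBOURNE", "YEALLFIELD", "YOOGWOOD", "SOCKLEIGH",
    "NOODSTOW", "WAXBOURNE", "BANBOURNE", "HARILLMERE", "CIGSHAW",
    "GETTBOURNE", "VIMWOOD", "CREARNLEIGH", "MOORNLEIGH", "LEMFORD",
    "YATTHURST", "TRORNSHAW", "NOLLFIELD", "FLOODDALE", "CRECKFIELD",
    "GARNMERE", "BOSSFORD", "GRODCOTT", "KERHURST", "TOORNBY", "CRUMCOTT",
    "KEANCOMBE", "TELLSHAW", "LINDFIELD", "DREAXWORTH", "WHARWORTH",
    "LOOGFIELD", "CEGWELL", "SOCKHURST", "PRURSHAW", "TINDCOTT",
    "DROOLLCOMBE", "NEASSCOTT", "HIRNHURST", "PROOMSTOW", "VENCOTT",
    "CRONDWELL", "YOXDALE", "LUDWOOD", "VIXWELL", "WHATTFORD", "SOOTTWOOD",
    "FOOCKMERE", "HOLLDALE", "FLULLWELL", "WHEADHURST", "STOSSHURST",
    "WHAMSHAW", "WOORNWOOD", "BAXLEIGH", "WHENMERE", "MOCKFIELD",
    "TROORNCOTT", "FUNDHURST", "PROOLLMERE", "WOXMERE", "FLODFORD",
    "STIXSHAW", "KUXCOTT", "MOOSSCOTT", "BREAGHURST", "TEASSWORTH",
    "VITTCOTT", "BINWELL", "GIXWOOD", "MOXCOMBE", "STUNWOOD", "HUMHURST",
    "YEAMWOOD", "STOOXCOTT", "YOODFORD", "CREAXCOTT", "GURDALE", "LALLTON",
    "YOSSMERE", "LUTTCOTT", "GOOMSHAW", "TERNTON", "YOTTSHAW", "KIGHURST",
    "SELLLEIGH", "FENDBOURNE", "TROOXMERE", "YUGFIELD", "CADMERE",
    "KERMERE", "VOCKWOOD", "WHONDLEIGH", "PRORCOMBE", "FERNSHAW",
    "STORNMERE", "CROOTTTON", "GRILLTON", "VEASSFIELD", "GRISSLEIGH",
    "WEMCOMBE", "DIRNSTOW", "FEARNFIELD", "DREAMBY", "WIMMERE", "FLEMFIELD",
    "HOTTTON", "FOOTTFIELD", "WHECKWORTH", "POONDTON", "YOOTTLEIGH",
    "MISSHURST", "POORNSHAW", "FLEANCOTT", "HAROSSCOMBE", "GRIGCOTT",
    "GEACKTON", "VICKBOURNE", "WUSSWORTH", "FEATTMERE", "TRETTWELL",
    "BUNDBOURNE", "WHESSTON", "LEALLBY", "DEDCOTT", "KUMSTOW", "YOOXWELL",
    "NAXHURST"
]

# Synthetic gazetteer: outward codes inside and outside the policing area.
IN_AREA_OUTWARDS = [f"AV{i}" for i in range(1, 15)] + [f"SM{i}" for i in range(1, 9)]
OUT_AREA_OUTWARDS = [f"ZX{i}" for i in range(1, 7)] + [f"QQ{i}" for i in range(1, 5)]

INWARD_LETTERS = "ABDEFGHJLNPQRSTUWXYZ"
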