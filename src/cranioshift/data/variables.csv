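code,name,element,definition
M1,Maximum cranial length,vault,Greatest length from glabella to opisthocranion
M5,Skull base length,vault,Distance from basion to nasion
M8,Maximum cranial breadth,vault,Greatest breadth perpendicular to the midsagittal plane
M9,Least frontal breadth,vault,Distance between the left and right frontotemporale
M11,Biauricular breadth,vault,Distance between the left and right auriculare
M11b,Biradicular breadth,vault,Distance between the left and right radiculare
M12,Biasterionic breadth,vault,Distance between the left and right asterion
M17,Basi-bregmatic height,vault,Distance from basion to bregma
M40,Basion-prosthion length,face,Distance from basion to prosthion
M45,Bizygomatic breadth,face,Distance between the left and right zygion
M48,Upper facial height,face,Distance from nasion to prosthion
M51,Orbital breadth,face,Distance from maxillofrontale to ektokonchion
M52,Orbital height,face,Greatest orbit height perpendicular to orbital breadth
M54,Nasal breadth,face,Greatest breadth of the nasal aperture
M55,Nasal height,face,Distance from nasion to nasospinale
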